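"""Implied covariance, ML discrepancy, model fitting and standardization."""

import numpy as np
import pandas as pd
import pytest

import twincycle as tc
from twincycle.path_model import Edge, PathModel, parse_model_spec
from twincycle.preprocess import CovarianceInput
from twincycle.sem_fit import (
    FitError,
    SingularSystemError,
    fit_model,
    implied_covariance,
    ml_discrepancy,
)


def chain_model():
    return parse_model_spec("m <- x [b1]\ny <- m [b2]\nexogenous: x")


def _cov(S, n, variables):
    return CovarianceInput(np.asarray(S, dtype=float), n, variables)


class TestImpliedCovariance:
    def test_zero_b_returns_psi(self):
        psi = np.array([1.0, 2.0, 0.5])
        np.testing.assert_allclose(implied_covariance(np.zeros((3, 3)), psi), np.diag(psi))

    def test_chain_hand_expansion(self):
        # x -> m -> y with coefficients b1, b2 and unit disturbances
        b1, b2 = 0.5, 0.4
        B = np.zeros((3, 3))
        B[1, 0], B[2, 1] = b1, b2
        Sigma = implied_covariance(B, np.ones(3))
        var_m = b1**2 + 1
        expected = np.array(
            [
                [1.0, b1, b1 * b2],
                [b1, var_m, b2 * var_m],
                [b1 * b2, b2 * var_m, b2**2 * var_m + 1],
            ]
        )
        np.testing.assert_allclose(Sigma, expected, atol=1e-12)

    def test_feedback_loop_matches_neumann_series(self):
        # a <-> b cycle: (I - B)^-1 = sum_k B^k converges for |b1 b2| < 1,
        # so Sigma = (sum_k B^k) Psi (sum_k B^k)^T at high truncation order
        B = np.array([[0.0, 0.4], [0.5, 0.0]])
        psi = np.array([1.0, 1.5])
        Sigma = implied_covariance(B, psi)
        A_series = np.zeros((2, 2))
        Bk = np.eye(2)
        for _ in range(60):
            A_series += Bk
            Bk = B @ Bk
        np.testing.assert_allclose(Sigma, (A_series * psi) @ A_series.T, atol=1e-8)

    def test_singular_system_rejected(self):
        B = np.array([[0.0, 2.0], [0.5, 0.0]])  # b1*b2 = 1
        with pytest.raises(SingularSystemError):
            implied_covariance(B, np.ones(2))


class TestMlDiscrepancy:
    def test_zero_at_equality(self, rng):
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_hand_value(self):
        # p = 1: ln 1 - ln 2 + 2/1 - 1 = 1 - ln 2
        f = ml_discrepancy(np.array([[2.0]]), np.array([[1.0]]))
        assert f == pytest.approx(1.0 - np.log(2.0), abs=1e-12)

    def test_strictly_positive_off_optimum(self):
        S = np.eye(3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            A = rng.normal(scale=0.2, size=(3, 3))
            Sigma = S + A @ A.T + 0.01 * np.eye(3)
            assert ml_discrepancy(S, Sigma) > 0

    def test_non_pd_input_named(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(FitError, match="Sigma"):
            ml_discrepancy(np.eye(2), bad)
        with pytest.raises(FitError, match="sample"):
            ml_discrepancy(bad, np.eye(2))


def _random_pd(rng, p, scale=1.0):
    A = rng.normal(size=(p, p))
    S = A @ A.T / p + scale * np.eye(p)
    return (S + S.T) / 2


def _ols_on_moments(S, parents, target):
    """Equation-wise least squares from moments: the ML solution for
    recursive models."""
    Spp = S[np.ix_(parents, parents)]
    return np.linalg.solve(Spp, S[np.ix_(parents, [target])]).ravel()


class TestFitModel:
    def test_single_edge_closed_form(self, rng):
        S = _random_pd(rng, 2)
        model = parse_model_spec("y <- x [b]\nexogenous: x")
        fit = fit_model(model, _cov(S, 200, ["x", "y"]), compute_se=False)
        assert fit.estimate("b") == pytest.approx(S[0, 1] / S[0, 0], abs=1e-8)

    def test_saturated_recursive_model_reproduces_s(self, rng):
        S = _random_pd(rng, 3)
        model = parse_model_spec(
            "b <- a [e1]\nc <- a [e2]\nc <- b [e3]\nexogenous: a"
        )
        assert model.degrees_of_freedom == 0
        fit = fit_model(model, _cov(S, 150, ["a", "b", "c"]), compute_se=False)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.implied, S, atol=1e-6)

    def test_recursive_models_match_ols_on_moments(self):
        # ML path estimates for acyclic systems equal per-equation least
        # squares computed from the covariance matrix
        model = parse_model_spec(
            "m <- x [b1]\ny <- m [b2]\ny <- x [b3]\nz <- y [b4]\nexogenous: x"
        )
        order = ["x", "m", "y", "z"]
        idx = {v: i for i, v in enumerate(order)}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            S = _random_pd(rng, 4)
            fit = fit_model(model, _cov(S, 300, order), compute_se=False)
            np.testing.assert_allclose(
                [fit.estimate("b1")], _ols_on_moments(S, [idx["x"]], idx["m"]), atol=1e-6
            )
            np.testing.assert_allclose(
                [fit.estimate("b3"), fit.estimate("b2")],
                _ols_on_moments(S, [idx["x"], idx["m"]], idx["y"]),
                atol=1e-6,
            )
            np.testing.assert_allclose(
                [fit.estimate("b4")], _ols_on_moments(S, [idx["y"]], idx["z"]), atol=1e-6
            )

    def test_cyclic_truth_recovered_at_large_n(self):
        # simulate from the full cyclic TC-PA system and refit
        spec = tc.SyntheticCohortSpec(cohort=1, model_name="TC-PA", n=100_000, seed=11)
        B, psi, _ = tc.generating_truth(spec)
        model = spec.model
        scores = tc.simulate_structural_system(B, psi, spec.n, seed=spec.seed)
        table = pd.DataFrame(scores, columns=model.nodes)
        fit = fit_model(model, tc.covariance_input(table, model.nodes), compute_se=False)
        idx = {n: i for i, n in enumerate(model.nodes)}
        for e in model.edges:
            assert fit.estimate(e.label) == pytest.approx(
                B[idx[e.target], idx[e.source]], abs=0.02
            )

    def test_negative_df_rejected(self, rng):
        # 2-cycle with free disturbances: 4 parameters but only 3 moments
        model = PathModel(
            nodes=["x", "y"],
            edges=[Edge("b", "x", "y"), Edge("b2", "y", "x")],
        )
        with pytest.raises(FitError, match="df"):
            fit_model(model, _cov(_random_pd(rng, 2), 100, ["x", "y"]))

    def test_acov_is_symmetric_psd(self, cohort1_fit):
        acov = cohort1_fit.acov
        np.testing.assert_allclose(acov, acov.T, atol=1e-12)
        assert np.linalg.eigvalsh(acov).min() >= -1e-12

    def test_wald_table_shape(self, cohort1_fit):
        table = cohort1_fit.to_table()
        assert len(table) == 21
        assert set(["outcome", "parent", "edge", "estimate", "beta_std", "se", "z", "p"]) <= set(
            table.columns
        )
        assert (table["se"] > 0).all()


class TestStandardizedSolution:
    def test_equals_raw_when_variances_are_unit(self):
        spec = tc.SyntheticCohortSpec(cohort=1, n=725, seed=5)
        B, psi, Sigma = tc.generating_truth(spec)
        np.testing.assert_allclose(np.diag(Sigma), 1.0, atol=1e-10)
        model = spec.model
        data = _cov(Sigma, 725, model.nodes)
        fit = fit_model(model, data, compute_se=False)
        std = fit.standardized_estimates()
        for i, e in enumerate(model.edges):
            assert std[e.label] == pytest.approx(float(fit.theta[i]), abs=1e-6)

    def test_chain_hand_value(self, rng):
        # b1 = 0.5, b2 = 0.4: beta_std(m -> y) = 0.4 sqrt(1.25) / sqrt(1.2)
        B = np.zeros((3, 3))
        B[1, 0], B[2, 1] = 0.5, 0.4
        Sigma = implied_covariance(B, np.ones(3))
        model = chain_model()
        fit = fit_model(model, _cov(Sigma, 500, ["x", "m", "y"]), compute_se=False)
        std = fit.standardized_estimates()
        expected = 0.4 * np.sqrt(1.25) / np.sqrt(0.4**2 * 1.25 + 1)
        assert std["b2"] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.4082, abs=2e-4)

    def test_invariant_to_column_rescaling(self, rng):
        S = _random_pd(rng, 3)
        model = chain_model()
        order = ["x", "m", "y"]
        fit1 = fit_model(model, _cov(S, 400, order), compute_se=False)
        D = np.diag([10.0, 1.0, 1.0])
        fit2 = fit_model(model, _cov(D @ S @ D, 400, order), compute_se=False)
        std1, std2 = fit1.standardized_estimates(), fit2.standardized_estimates()
        for label in std1:
            assert std1[label] == pytest.approx(std2[label], abs=1e-6)
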
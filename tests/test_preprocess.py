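"""Rank-normal transform, residualisation, correlations, covariance input."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from twincycle.preprocess import (
    CovarianceInput,
    PreprocessError,
    covariance_input,
    pairwise_correlations,
    rank_inverse_normal,
    residualize,
)


class TestRankInverseNormal:
    def test_matches_quantile_function_oracle(self):
        # Blom scores for ranks 1..3 of [1.2, 2.0, 3.1]: Phi^-1((r - 3/8)/3.25)
        out = rank_inverse_normal([3.1, 1.2, 2.0], offset=0.375)
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [0.869, -0.869, 0.000], atol=5e-4)

    def test_tie_free_scores_are_antisymmetric(self, rng):
        x = rng.normal(size=31)
        out = rank_inverse_normal(x)
        assert abs(out.sum()) < 1e-10

    def test_order_preserving_within_stratum(self, rng):
        x = np.sort(rng.normal(size=40))
        out = rank_inverse_normal(x)
        assert np.all(np.diff(out) > 0)

    def test_ties_get_average_ranks(self):
        out = rank_inverse_normal([1.0, 2.0, 2.0, 3.0])
        assert out[1] == out[2]
        assert out[0] < out[1] < out[3]

    def test_stratified_transform_is_per_stratum(self, rng):
        x = np.concatenate([rng.normal(10, 1, 30), rng.normal(-5, 1, 30)])
        strata = np.repeat(["a", "b"], 30)
        out = rank_inverse_normal(x, strata)
        # each stratum separately centred, so the shift between groups vanishes
        assert abs(out[:30].mean()) < 1e-10
        assert abs(out[30:].mean()) < 1e-10

    def test_missing_values_propagate(self):
        out = rank_inverse_normal([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2, 3]]).all()

    def test_small_stratum_error_names_stratum(self):
        with pytest.raises(PreprocessError, match="tiny"):
            rank_inverse_normal([1.0, 2.0, 3.0], ["a", "a", "tiny"])

    def test_constant_stratum_rejected(self):
        with pytest.raises(PreprocessError, match="constant"):
            rank_inverse_normal([5.0, 5.0, 5.0])

    def test_offset_bounds_checked(self):
        with pytest.raises(PreprocessError):
            rank_inverse_normal([1.0, 2.0], offset=0.7)

    @pytest.mark.parametrize("n", [50, 200])
    def test_scores_approximate_standard_normal(self, n, rng):
        out = rank_inverse_normal(rng.exponential(size=n))
        assert abs(out.mean()) < 0.02
        assert 0.9 <= out.std(ddof=1) <= 1.1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        values=arrays(
            float,
            st.integers(50, 120),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
            unique=True,
        ),
        offset=st.floats(0.0, 0.5),
    )
    def test_property_rank_preserving_and_calibrated(self, values, offset):
        out = rank_inverse_normal(values, offset=offset)
        order = np.argsort(values)
        assert np.all(np.diff(out[order]) > 0)
        assert abs(out.mean()) < 0.02
        assert 0.9 <= out.std(ddof=1) <= 1.1


class TestResidualize:
    @staticmethod
    def _toy_table(rng):
        x = rng.normal(size=6)
        y = 2 * x + rng.normal(scale=0.1, size=6)
        return pd.DataFrame({"y": y, "x": x})

    def test_matches_hand_normal_equations(self, rng):
        table = self._toy_table(rng)
        resid = residualize(table, ["y"], ["x"])
        X = np.column_stack([np.ones(6), table["x"]])
        beta = np.linalg.solve(X.T @ X, X.T @ table["y"].to_numpy())
        np.testing.assert_allclose(
            resid["y"].to_numpy(), table["y"].to_numpy() - X @ beta, atol=1e-10
        )

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 80
        table = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "age": rng.normal(60, 6, n),
                "centre": pd.Categorical(rng.choice(list("abcd"), n)),
            }
        )
        resid = residualize(table, ["y"], ["age", "centre"])["y"].to_numpy()
        assert abs(resid @ (table["age"] - table["age"].mean())) < 1e-8 * n
        for level in "bcd":
            dummy = (table["centre"] == level).to_numpy(dtype=float)
            assert abs(resid @ (dummy - dummy.mean())) < 1e-8 * n

    def test_orthogonal_covariate_leaves_centred_target(self):
        # covariate orthogonal to the centred target: residual = centred target
        y = np.array([1.0, -1.0, 2.0, -2.0])
        x = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to y and to constant
        table = pd.DataFrame({"y": y, "x": x})
        resid = residualize(table, ["y"], ["x"])
        np.testing.assert_allclose(resid["y"], y - y.mean(), atol=1e-12)

    def test_idempotent(self, rng):
        n = 60
        table = pd.DataFrame(
            {"y": rng.normal(size=n), "a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        once = residualize(table, ["y"], ["a", "b"])
        again = residualize(pd.concat([once, table[["a", "b"]]], axis=1), ["y"], ["a", "b"])
        np.testing.assert_allclose(once["y"], again["y"], atol=1e-10)

    def test_too_few_rows_rejected(self, rng):
        table = pd.DataFrame({"y": rng.normal(size=3), "a": rng.normal(size=3),
                              "b": rng.normal(size=3), "c": rng.normal(size=3)})
        with pytest.raises(PreprocessError, match="rows"):
            residualize(table, ["y"], ["a", "b", "c"])

    def test_duplicate_covariate_column_pruned(self, rng):
        n = 30
        a = rng.normal(size=n)
        table = pd.DataFrame({"y": rng.normal(size=n), "a": a, "a2": a.copy()})
        resid = residualize(table, ["y"], ["a", "a2"])
        single = residualize(table, ["y"], ["a"])
        np.testing.assert_allclose(resid["y"], single["y"], atol=1e-8)


class TestPairwiseCorrelations:
    def test_hand_computed_pair(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        table = pd.DataFrame({"x": x, "y": y})
        corr = pairwise_correlations(table)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert corr.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
        assert corr.loc["x", "x"] == 1.0

    def test_negated_column(self, rng):
        x = rng.normal(size=20)
        corr = pairwise_correlations(pd.DataFrame({"x": x, "neg": -x}))
        assert corr.loc["x", "neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric(self, rng):
        table = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        corr = pairwise_correlations(table)
        np.testing.assert_allclose(corr, corr.T)

    def test_constant_column_gives_missing_not_zero(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
        corr = pairwise_correlations(table)
        assert np.isnan(corr.loc["x", "c"])
        assert np.isnan(corr.loc["c", "c"])

    def test_pairwise_complete_rows_used(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.1, size=12)
        y[:3] = np.nan
        corr = pairwise_correlations(pd.DataFrame({"x": x, "y": y}))
        expected = np.corrcoef(x[3:], y[3:])[0, 1]
        assert corr.loc["x", "y"] == pytest.approx(expected, abs=1e-12)


class TestCovarianceInput:
    def test_hand_computation_n_minus_one(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 6.0], "b": [2.0, 1.0, 5.0, 4.0], "c": [0.0, 1.0, -1.0, 2.0]}
        )
        data = covariance_input(table)
        X = table.to_numpy()
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(data.S, Xc.T @ Xc / 3.0, atol=1e-12)
        assert data.n == 4

    def test_listwise_deletion_recorded(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        table.loc[:4, "a"] = np.nan
        data = covariance_input(table)
        assert data.n == 25

    def test_symmetry_exact(self, rng):
        table = pd.DataFrame(rng.normal(size=(40, 5)))
        table.columns = [f"v{i}" for i in range(5)]
        data = covariance_input(table)
        assert np.array_equal(data.S, data.S.T)

    def test_standardized_columns_near_unit_diagonal(self, rng):
        z = rng.normal(size=(500, 3))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        data = covariance_input(pd.DataFrame(z, columns=list("abc")))
        np.testing.assert_allclose(np.diag(data.S), 1.0, atol=1e-10)

    def test_non_positive_definite_rejected_with_eigenvalue(self, rng):
        x = rng.normal(size=20)
        table = pd.DataFrame({"x": x, "twice": 2 * x})
        with pytest.raises(PreprocessError, match="eigenvalue"):
            covariance_input(table)

    def test_iid_normal_converges_to_identity(self):
        # off-diagonal entries shrink at the 4/sqrt(N) parametric rate
        failures = 0
        n = 2000
        n_seeds = 100
        for seed in range(n_seeds):
            z = np.random.default_rng(seed).normal(size=(n, 4))
            data = covariance_input(pd.DataFrame(z, columns=list("abcd")))
            off = data.S - np.diag(np.diag(data.S))
            if np.abs(off).max() >= 4 / np.sqrt(n):
                failures += 1
        # the bound holds with probability >= 0.99 per seed
        assert failures <= 4

    def test_reorder_permutes_consistently(self, rng):
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        data = covariance_input(table)
        re = data.reorder(["c", "a", "b"])
        assert re.variables == ["c", "a", "b"]
        assert re.S[0, 1] == data.S[2, 0]

    def test_mismatched_shape_rejected(self):
        with pytest.raises(PreprocessError):
            CovarianceInput(np.eye(3), 10, ["a", "b"])
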
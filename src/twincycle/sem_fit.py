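"""Maximum-likelihood covariance-structure estimation for path models.

The structural system is ``y = B y + zeta`` with ``B`` the (possibly cyclic)
matrix of path coefficients and ``zeta`` mean-zero disturbances with diagonal
covariance ``Psi``.  Its implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T,

and the ML discrepancy against a sample covariance ``S`` (order ``p``) is

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,

minimised over the free entries of ``B`` and ``Psi``.  The fit statistic is
``chi2 = (N - 1) F_ML`` at the optimum; standard errors come from the
numerically differentiated Hessian of F_ML via ``ACOV = (2/(N-1)) H^-1``.

Exogenous variables follow the fixed-x convention by default: their
disturbance variance is fixed at the sample variance rather than estimated,
which reproduces that moment exactly.

The gradient of F_ML is analytic.  With ``A = (I - B)^-1`` and
``M = Sigma^-1 - Sigma^-1 S Sigma^-1``:

    dF/dB[t, s]   = 2 (Sigma M A)[s, t]
    dF/dPsi[k, k] = (A^T M A)[k, k]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .path_model import PathModel
from .preprocess import CovarianceInput

_PSI_FLOOR = 1e-6
_BAD_VALUE = 1e10


class FitError(RuntimeError):
    pass


class SingularSystemError(FitError):
    """(I - B) is singular: the structural system has no reduced form."""


@dataclass
class ParameterSet:
    """Mapping between a free-parameter vector and the (B, Psi) matrices.

    ``b_cells`` holds the (target_index, source_index) cell per free edge, in
    edge order; ``psi_cells`` the diagonal indices of free disturbance
    variances.  Fixed cells (exogenous variances under fixed-x) are stored in
    ``fixed_psi`` and never touched by the optimiser.
    """

    model: PathModel
    b_cells: list[tuple[int, int]]
    psi_cells: list[int]
    fixed_psi: dict[int, float] = field(default_factory=dict)

    @classmethod
    def for_model(cls, model: PathModel, S: np.ndarray | None = None) -> "ParameterSet":
        idx = {n: i for i, n in enumerate(model.nodes)}
        b_cells = [(idx[e.target], idx[e.source]) for e in model.edges]
        if model.free_exogenous_variance:
            psi_cells = list(range(model.n_nodes))
            fixed = {}
        else:
            psi_cells = [idx[n] for n in model.endogenous]
            fixed = {}
            for x in model.exogenous:
                if S is None:
                    raise FitError(
                        "fixed-x convention needs a sample covariance to fix "
                        f"the variance of exogenous node {x!r}"
                    )
                fixed[idx[x]] = float(S[idx[x], idx[x]])
        return cls(model=model, b_cells=b_cells, psi_cells=psi_cells, fixed_psi=fixed)

    @property
    def n_free(self) -> int:
        return len(self.b_cells) + len(self.psi_cells)

    @property
    def names(self) -> list[str]:
        edge_names = [e.label for e in self.model.edges]
        psi_names = [f"psi_{self.model.nodes[k]}" for k in self.psi_cells]
        return edge_names + psi_names

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """theta -> (B, psi_diagonal)."""
        p = self.model.n_nodes
        B = np.zeros((p, p))
        nb = len(self.b_cells)
        for (t, s), val in zip(self.b_cells, theta[:nb]):
            B[t, s] = val
        psi = np.zeros(p)
        for k, val in zip(self.psi_cells, theta[nb:]):
            psi[k] = val
        for k, val in self.fixed_psi.items():
            psi[k] = val
        return B, psi

    def start_values(self, S: np.ndarray) -> np.ndarray:
        theta = np.zeros(self.n_free)
        nb = len(self.b_cells)
        for j, k in enumerate(self.psi_cells):
            theta[nb + j] = 0.5 * S[k, k]
        return theta

    def bounds(self) -> list[tuple[float | None, float | None]]:
        nb = len(self.b_cells)
        return [(None, None)] * nb + [(_PSI_FLOOR, None)] * len(self.psi_cells)


def implied_covariance(B: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Sigma = (I - B)^-1 Psi (I - B)^-T for diagonal Psi given as a vector."""
    p = B.shape[0]
    ImB = np.eye(p) - B
    det = np.linalg.det(ImB)
    if abs(det) < 1e-12:
        raise SingularSystemError(
            "I - B is singular; the structural system is not invertible"
        )
    A = np.linalg.inv(ImB)
    Sigma = (A * psi) @ A.T
    return (Sigma + Sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p; >= 0, zero iff equal."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise FitError("S and Sigma must have the same order")
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or np.linalg.eigvalsh(S).min() <= 0:
        raise FitError("sample covariance S is not positive definite")
    if sign_m <= 0 or np.linalg.eigvalsh(Sigma).min() <= 0:
        raise FitError("implied covariance Sigma is not positive definite")
    f = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(Sigma))) - p
    return max(f, 0.0)


def _objective(theta: np.ndarray, pset: ParameterSet, S: np.ndarray, logdet_s: float):
    """(F_ML, gradient); invalid points return a large value so line searches
    retreat."""
    p = S.shape[0]
    B, psi = pset.unpack(theta)
    ImB = np.eye(p) - B
    try:
        A = np.linalg.inv(ImB)
    except np.linalg.LinAlgError:
        return _BAD_VALUE, np.zeros_like(theta)
    if not np.all(np.isfinite(A)):
        return _BAD_VALUE, np.zeros_like(theta)
    Sigma = (A * psi) @ A.T
    Sigma = (Sigma + Sigma.T) / 2.0
    sign, logdet_m = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return _BAD_VALUE, np.zeros_like(theta)
    try:
        Sigma_inv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return _BAD_VALUE, np.zeros_like(theta)
    f = logdet_m - logdet_s + float(np.sum(S * Sigma_inv)) - p
    if not np.isfinite(f):
        return _BAD_VALUE, np.zeros_like(theta)

    M = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    SMA = Sigma @ M @ A
    AMA = A.T @ M @ A
    grad = np.empty_like(theta)
    nb = len(pset.b_cells)
    for j, (t, s) in enumerate(pset.b_cells):
        grad[j] = 2.0 * SMA[s, t]
    for j, k in enumerate(pset.psi_cells):
        grad[nb + j] = AMA[k, k]
    return f, grad


@dataclass
class FitResult:
    """A converged ML fit of a path model to a covariance matrix."""

    model: PathModel
    data: CovarianceInput
    pset: ParameterSet
    theta: np.ndarray
    f_ml: float
    chi2: float
    df: int
    converged: bool
    gradient_norm: float
    n_iterations: int
    n_restarts_used: int
    acov: np.ndarray | None = None
    se: np.ndarray | None = None
    heywood: bool = False

    # -- derived views -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def parameter_names(self) -> list[str]:
        return self.pset.names

    @property
    def B(self) -> np.ndarray:
        return self.pset.unpack(self.theta)[0]

    @property
    def psi(self) -> np.ndarray:
        return self.pset.unpack(self.theta)[1]

    @property
    def implied(self) -> np.ndarray:
        return implied_covariance(self.B, self.psi)

    @property
    def wald_z(self) -> np.ndarray:
        if self.se is None:
            raise FitError("standard errors were not computed for this fit")
        return self.theta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def estimate(self, edge_label: str) -> float:
        return float(self.theta[self._edge_index(edge_label)])

    def _edge_index(self, edge_label: str) -> int:
        for i, e in enumerate(self.model.edges):
            if e.label == edge_label:
                return i
        raise KeyError(f"no edge labelled {edge_label!r}")

    def edge_p_value(self, edge_label: str) -> float:
        return float(self.wald_p[self._edge_index(edge_label)])

    def standardized_estimates(self) -> dict[str, float]:
        return standardized_solution(self)

    def chi2_p_value(self) -> float:
        return float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else float("nan")

    def to_table(self):
        """Per-edge report: outcome node, parent node, edge, raw and
        standardized estimates, SE, z, p."""
        import pandas as pd

        std = self.standardized_estimates()
        rows = []
        for i, e in enumerate(self.model.edges):
            row = {
                "outcome": e.target,
                "parent": e.source,
                "edge": e.label,
                "estimate": float(self.theta[i]),
                "beta_std": std[e.label],
            }
            if self.se is not None:
                row["se"] = float(self.se[i])
                row["z"] = float(self.wald_z[i])
                row["p"] = float(self.wald_p[i])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "model": self.model.name,
            "n": self.n,
            "chi2": self.chi2,
            "df": self.df,
            "f_ml": self.f_ml,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "heywood": self.heywood,
            "estimates": {nm: float(v) for nm, v in zip(self.parameter_names, self.theta)},
            "standardized": self.standardized_estimates(),
        }
        if self.se is not None:
            out["se"] = {nm: float(v) for nm, v in zip(self.parameter_names, self.se)}
            out["p"] = {nm: float(v) for nm, v in zip(self.parameter_names, self.wald_p)}
        return out


def fit_model(
    model: PathModel,
    data: CovarianceInput,
    compute_se: bool = True,
    n_restarts: int = 10,
    gtol: float = 1e-8,
    seed: int = 0,
    n_minus_one: bool = True,
) -> FitResult:
    """Fit a path model to a sample covariance by maximum likelihood.

    Starts from zero path coefficients and half the sample variances as
    disturbances; on non-convergence, up to ``n_restarts`` seeded jittered
    restarts are attempted.  ``chi2`` uses the ``(N - 1)`` Wishart scaling
    unless ``n_minus_one`` is False.

    Raises
    ------
    FitError
        if no restart converges, or df < 0.
    """
    data = data.reorder(model.nodes) if data.variables != model.nodes else data
    S = data.S
    df = model.degrees_of_freedom
    if df < 0:
        raise FitError(f"model has negative df ({df}); it is not identifiable")
    eig_min = float(np.linalg.eigvalsh(S).min())
    if eig_min <= 0:
        raise FitError(f"sample covariance not positive definite (min eig {eig_min:.3e})")

    pset = ParameterSet.for_model(model, S)
    _, logdet_s = np.linalg.slogdet(S)
    bounds = pset.bounds()
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(n_restarts + 1):
        theta0 = pset.start_values(S)
        if attempt > 0:
            nb = len(pset.b_cells)
            theta0[:nb] += rng.normal(scale=0.2, size=nb)
            theta0[nb:] *= rng.uniform(0.5, 2.0, size=len(pset.psi_cells))
        res = optimize.minimize(
            _objective,
            theta0,
            args=(pset, S, logdet_s),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": gtol},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = np.isfinite(res.fun) and res.fun < _BAD_VALUE / 2 and gnorm < 1e-4
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm, attempt)
        if ok:
            best = (res, gnorm, attempt)
            break
    res, gnorm, attempt = best
    converged = np.isfinite(res.fun) and res.fun < _BAD_VALUE / 2 and gnorm < 1e-4
    if not converged:
        raise FitError(
            f"optimisation failed after {attempt + 1} start(s); "
            f"best F_ML = {res.fun:.6g}, gradient norm = {gnorm:.3g}"
        )

    theta = res.x
    f_ml = max(float(res.fun), 0.0)
    scale = data.n - 1 if n_minus_one else data.n
    chi2 = scale * f_ml

    nb = len(pset.b_cells)
    heywood = bool(np.any(theta[nb:] <= _PSI_FLOOR * 1.0001))
    if heywood:
        warnings.warn(
            "disturbance variance pinned at its lower bound (Heywood case)",
            RuntimeWarning,
            stacklevel=2,
        )

    fit = FitResult(
        model=model,
        data=data,
        pset=pset,
        theta=theta,
        f_ml=f_ml,
        chi2=chi2,
        df=df,
        converged=True,
        gradient_norm=gnorm,
        n_iterations=int(res.nit),
        n_restarts_used=attempt,
        heywood=heywood,
    )
    if compute_se:
        H = _hessian(theta, pset, S, logdet_s)
        acov = _acov_from_hessian(H, scale)
        fit.acov = acov
        fit.se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    return fit


def _hessian(theta, pset, S, logdet_s, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian of F_ML by central differences of the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = _objective(tp, pset, S, logdet_s)
        _, gm = _objective(tm, pset, S, logdet_s)
        H[:, j] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0


def _acov_from_hessian(H: np.ndarray, scale: float) -> np.ndarray:
    """ACOV = (2/scale) H^-1, projected to the nearest PSD matrix if the
    numerical Hessian has tiny negative eigenvalues."""
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
    acov = (2.0 / scale) * Hinv
    acov = (acov + acov.T) / 2.0
    w, V = np.linalg.eigh(acov)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        acov = (V * w) @ V.T
    return acov


def standardized_solution(fit: FitResult) -> dict[str, float]:
    """Standardized path coefficient per edge label.

    ``beta_std = b * sigma_source / sigma_target`` with model-implied SDs
    from ``diag Sigma(theta)``.  Invariant to rescaling any observed
    variable by a positive constant.
    """
    Sigma = fit.implied
    sd = np.sqrt(np.diag(Sigma))
    if np.any(sd <= 0):
        raise FitError("implied variance is zero; standardization undefined")
    idx = {n: i for i, n in enumerate(fit.model.nodes)}
    out: dict[str, float] = {}
    for i, e in enumerate(fit.model.edges):
        out[e.label] = float(fit.theta[i] * sd[idx[e.source]] / sd[idx[e.target]])
    return out


def standardized_acov(fit: FitResult, edge_labels: list[str]) -> np.ndarray:
    """ACOV of the named edges' standardized coefficients.

    Scales the raw-edge block of the parameter covariance by the implied
    SD ratios, treating the implied SDs as constants in the linearisation.
    """
    if fit.acov is None:
        raise FitError("fit has no parameter covariance; refit with compute_se=True")
    Sigma = fit.implied
    sd = np.sqrt(np.diag(Sigma))
    idx = {n: i for i, n in enumerate(fit.model.nodes)}
    rows = [fit._edge_index(lbl) for lbl in edge_labels]
    ratios = np.array(
        [
            sd[idx[fit.model.edges[r].source]] / sd[idx[fit.model.edges[r].target]]
            for r in rows
        ]
    )
    block = fit.acov[np.ix_(rows, rows)]
    return block * np.outer(ratios, ratios)
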
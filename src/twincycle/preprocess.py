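"""Preprocessing: stratified rank-inverse-normal transform, residualisation,
pairwise correlations, and covariance-matrix construction.

The analysis pipeline transforms each continuous variable to normal scores
within strata (sex; sex x treatment group in the diabetes cohort), removes
putative confounders by two-step residual regression (OLS on age, study
centre and dietary intake variables, keeping the residuals), and summarises
the residualised variables by their sample covariance matrix, which is what
the structural models are fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PreprocessError(ValueError):
    pass


def rank_inverse_normal(
    values,
    strata=None,
    offset: float = 3.0 / 8.0,
) -> np.ndarray:
    """Stratified rank-based inverse-normal (Blom) transform.

    Within each stratum, non-missing values are replaced by
    ``Phi^-1((r - c) / (n - 2c + 1))`` where ``r`` is the average rank
    (ties averaged), ``n`` the stratum's non-missing count and ``c`` the
    rank offset (Blom's ``c = 3/8`` by default).  The result has mean 0 and
    SD close to 1 within each stratum.  Missing inputs map to missing
    outputs; the transform is order-preserving within a stratum.

    Parameters
    ----------
    values
        1-d array-like of continuous measurements; NaN marks missing.
    strata
        Optional stratum label per value; ``None`` treats all values as one
        stratum.
    offset
        Rank offset ``c`` in ``[0, 0.5]``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise PreprocessError("values must be one-dimensional")
    if not 0.0 <= offset <= 0.5:
        raise PreprocessError(f"offset must lie in [0, 0.5], got {offset}")
    if strata is None:
        labels = np.zeros(x.shape[0], dtype=int)
    else:
        labels = np.asarray(strata)
        if labels.shape[0] != x.shape[0]:
            raise PreprocessError("strata must match values in length")

    out = np.full_like(x, np.nan)
    for stratum in pd.unique(labels):
        in_stratum = labels == stratum
        obs = in_stratum & ~np.isnan(x)
        n = int(obs.sum())
        if n < 2:
            raise PreprocessError(
                f"stratum {stratum!r} has {n} non-missing value(s); need at least 2"
            )
        vals = x[obs]
        if np.all(vals == vals[0]):
            raise PreprocessError(
                f"stratum {stratum!r} is constant; normal scores are undefined"
            )
        ranks = stats.rankdata(vals, method="average")
        out[obs] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def _dummy_code(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Design-matrix columns for covariates; categoricals dummy-coded
    against their first level as reference."""
    pieces: list[pd.DataFrame] = []
    for cov in covariates:
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            pieces.append(col.astype(float).to_frame(cov))
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            pieces.append(dummies)
    return pd.concat(pieces, axis=1)


def residualize(
    table: pd.DataFrame,
    targets: list[str],
    covariates: list[str],
) -> pd.DataFrame:
    """Residuals of each target from OLS on an intercept plus covariates.

    Categorical covariates are dummy-coded with the first level as the
    reference.  Exactly collinear design columns are dropped (and reported
    in the error if the design stays rank-deficient).  Rows with any
    missing value among targets or covariates propagate NaN residuals for
    the affected target rows only; the regression itself uses rows complete
    for that target and all covariates.

    Returns a DataFrame of residuals with the target column names,
    preserving the input index.
    """
    missing = [c for c in targets + covariates if c not in table.columns]
    if missing:
        raise PreprocessError(f"columns not in table: {missing}")

    design = _dummy_code(table, covariates)
    design.insert(0, "const", 1.0)

    resid = pd.DataFrame(index=table.index, columns=targets, dtype=float)
    for target in targets:
        y = table[target].astype(float)
        rows = y.notna() & design.notna().all(axis=1)
        X = design.loc[rows].to_numpy()
        yy = y.loc[rows].to_numpy()
        if X.shape[0] <= X.shape[1]:
            raise PreprocessError(
                f"{target}: {X.shape[0]} rows for {X.shape[1]} design columns"
            )
        # prune exactly collinear columns via pivoted QR
        q, r, piv = _qr_with_pivot(X)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        rank = int((np.abs(np.diag(r)) > tol).sum())
        keep = np.sort(piv[:rank])
        dropped = [design.columns[j] for j in np.sort(piv[rank:])]
        if "const" in dropped:
            raise PreprocessError(
                f"{target}: design rank-deficient; dropped columns {dropped}"
            )
        Xk = X[:, keep]
        beta, _, mat_rank, _ = np.linalg.lstsq(Xk, yy, rcond=None)
        if mat_rank < Xk.shape[1]:
            raise PreprocessError(
                f"{target}: design still rank-deficient after dropping {dropped}"
            )
        resid.loc[rows, target] = yy - Xk @ beta
    return resid


def _qr_with_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def pairwise_correlations(table: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pearson correlation matrix on pairwise-complete observations.

    Constant columns yield missing (NaN) correlations rather than 0; the
    diagonal is exactly 1 for non-degenerate columns.
    """
    numeric = table.astype(float)
    corr = numeric.corr(method="pearson", min_periods=min_periods)
    for col in numeric.columns:
        x = numeric[col].dropna()
        if len(x) >= min_periods and x.nunique() > 1:
            corr.loc[col, col] = 1.0
        else:
            corr.loc[col, col] = np.nan
    return corr


@dataclass
class CovarianceInput:
    """A sample covariance matrix with its sample size and variable order."""

    S: np.ndarray
    n: int
    variables: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.variables)
        if self.S.shape != (p, p):
            raise PreprocessError(
                f"covariance is {self.S.shape} but {p} variables are named"
            )
        if not np.allclose(self.S, self.S.T):
            raise PreprocessError("covariance matrix is not symmetric")

    @property
    def p(self) -> int:
        return len(self.variables)

    def reorder(self, variables: list[str]) -> "CovarianceInput":
        idx = [self.variables.index(v) for v in variables]
        return CovarianceInput(self.S[np.ix_(idx, idx)], self.n, list(variables))


def covariance_input(
    table: pd.DataFrame,
    variables: list[str] | None = None,
) -> CovarianceInput:
    """Listwise-complete sample covariance (denominator N - 1) of the named
    variables, with a positive-definiteness check."""
    if variables is None:
        variables = list(table.columns)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise PreprocessError(f"variables not in table: {missing}")
    sub = table[variables].dropna()
    n = len(sub)
    p = len(variables)
    if n < p + 1:
        raise PreprocessError(f"need at least p+1 = {p + 1} complete rows, have {n}")
    S = np.cov(sub.to_numpy(dtype=float), rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    S = (S + S.T) / 2.0
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin <= 0.0:
        raise PreprocessError(
            f"sample covariance is not positive definite (min eigenvalue {eigmin:.3e})"
        )
    return CovarianceInput(S=S, n=n, variables=list(variables))
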
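"""Relative (CFI, TLI) and absolute (RMSEA) fit indices.

CFI and TLI compare the fitted model's chi-square against an independence
baseline (all covariances zero, variances free); RMSEA measures misfit per
degree of freedom.  These are reported alongside chi-square but carry no
formal decision role in this pipeline — model adequacy is judged by the
variable-randomised null test instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CovarianceInput
from .sem_fit import FitResult, ml_discrepancy


class FitIndexError(ValueError):
    pass


@dataclass
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    chi2_baseline: float
    df_baseline: int

    def to_dict(self) -> dict:
        return {
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "chi2_baseline": self.chi2_baseline,
            "df_baseline": self.df_baseline,
        }


def baseline_model_fit(data: CovarianceInput, n_minus_one: bool = True) -> tuple[float, int]:
    """Chi-square and df of the independence baseline Sigma_B = diag(S).

    The baseline frees every variance and fixes every covariance to zero, so
    df_B = p(p-1)/2 and F_ML has the closed form ln|diag S| - ln|S|
    (+ tr cancels: tr(S diag(S)^-1) = p).
    """
    p = data.p
    if p < 2:
        raise FitIndexError("baseline model needs at least 2 variables")
    scale = data.n - 1 if n_minus_one else data.n
    f_b = ml_discrepancy(data.S, np.diag(np.diag(data.S)))
    df_b = p * (p - 1) // 2
    return scale * f_b, df_b


def compute_fit_indices(
    fit: FitResult,
    baseline: tuple[float, int] | None = None,
) -> FitIndices:
    """CFI, TLI and RMSEA for a converged fit.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_B - df_B, chi2_M - df_M, 0)
    TLI = ((chi2_B/df_B) - (chi2_M/df_M)) / ((chi2_B/df_B) - 1)
    RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M (N - 1)))
    """
    if fit.df == 0:
        raise FitIndexError("fit indices are undefined for saturated models (df = 0)")
    if baseline is None:
        baseline = baseline_model_fit(fit.data)
    chi2_b, df_b = baseline
    chi2_m, df_m = fit.chi2, fit.df

    excess_m = max(chi2_m - df_m, 0.0)
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess_m / denom

    ratio_b = chi2_b / df_b
    tli = (ratio_b - chi2_m / df_m) / (ratio_b - 1.0) if ratio_b != 1.0 else float("nan")

    rmsea = float(np.sqrt(excess_m / (df_m * (fit.n - 1))))
    return FitIndices(
        cfi=float(cfi),
        tli=float(tli),
        rmsea=rmsea,
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_b),
    )
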
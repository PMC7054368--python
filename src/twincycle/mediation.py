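"""Coefficient-product (pathway) mediation on fitted path models.

An indirect effect along a directed path is the product of the fitted
standardized coefficients of its edges.  Pathways are screened by the
Baron–Kenny-style eligibility rule: a path is tested only when every direct
edge along it is individually statistically significant (two-sided Wald
p < alpha).  Standard errors come from the multivariate delta method on the
joint covariance of the path's edge coefficients; the Sobel independence
approximation is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .path_model import DirectedPath, PathModel, enumerate_directed_paths
from .sem_fit import FitError, FitResult, standardized_acov


class MediationError(ValueError):
    pass


@dataclass
class MediationEffect:
    """An indirect effect along one directed path, on the standardized scale."""

    path: DirectedPath
    estimate: float
    se: float
    z: float
    p: float
    eligible: bool
    failing_edge: str | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.path.nodes[-1],
            "edge_path": str(self.path),
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "eligible": self.eligible,
            "failing_edge": self.failing_edge,
        }


def _check_path_edges(fit: FitResult, path: DirectedPath) -> None:
    model_labels = {e.label for e in fit.model.edges}
    for lbl in path.edge_labels:
        if lbl not in model_labels:
            raise MediationError(
                f"path {path} traverses edge {lbl!r} absent from the fitted model"
            )


def eligible_pathways(
    fit: FitResult,
    paths: list[DirectedPath],
    alpha: float = 0.05,
) -> tuple[list[DirectedPath], list[tuple[DirectedPath, str]]]:
    """Partition paths into (eligible, ineligible-with-failing-edge).

    A path is eligible iff every traversed edge's two-sided Wald p-value is
    below ``alpha``; an ineligible path reports its first failing edge.
    """
    eligible: list[DirectedPath] = []
    ineligible: list[tuple[DirectedPath, str]] = []
    for path in paths:
        _check_path_edges(fit, path)
        failing = None
        for lbl in path.edge_labels:
            if fit.edge_p_value(lbl) >= alpha:
                failing = lbl
                break
        if failing is None:
            eligible.append(path)
        else:
            ineligible.append((path, failing))
    return eligible, ineligible


def indirect_effect(
    fit: FitResult,
    path: DirectedPath,
    method: str = "delta",
    eligible: bool = True,
    failing_edge: str | None = None,
) -> MediationEffect:
    """Product-of-coefficients indirect effect with its standard error.

    The estimate is the product of the fitted standardized coefficients
    along the path.  ``method="delta"`` propagates the joint covariance of
    the path's coefficients (gradient of the product); ``method="sobel"``
    uses the classical independence approximation (two-edge paths only).
    """
    _check_path_edges(fit, path)
    if fit.acov is None:
        raise MediationError(
            "fit has no parameter covariance (non-converged or compute_se=False)"
        )
    labels = list(path.edge_labels)
    std = fit.standardized_estimates()
    betas = np.array([std[lbl] for lbl in labels])
    estimate = float(np.prod(betas))

    acov = standardized_acov(fit, labels)
    grad = np.array(
        [np.prod(np.delete(betas, i)) if betas.size > 1 else 1.0
         for i in range(betas.size)]
    )
    if method == "delta":
        var = float(grad @ acov @ grad)
    elif method == "sobel":
        if len(labels) != 2:
            raise MediationError("the Sobel approximation applies to two-edge paths")
        a, b = betas
        sa, sb = np.sqrt(np.diag(acov))
        var = float(a**2 * sb**2 + b**2 * sa**2)
    else:
        raise MediationError(f"unknown SE method {method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    z = estimate / se if se > 0 else float("nan")
    p = 2.0 * float(stats.norm.sf(abs(z))) if se > 0 else float("nan")
    return MediationEffect(
        path=path, estimate=estimate, se=se, z=z, p=p,
        eligible=eligible, failing_edge=failing_edge,
    )


def mediation_table(
    fit: FitResult,
    source: str,
    sinks: list[str],
    alpha: float = 0.05,
    max_length: int | None = None,
    include_direct: bool = False,
):
    """Screen and quantify every simple path from ``source`` to each sink.

    Direct (single-edge) paths are excluded by default — they are edge
    estimates, not mediated effects.  Returns a DataFrame with one row per
    enumerated path, flagging eligibility and naming the failing edge for
    ineligible paths; estimates are reported for eligible paths.
    """
    import pandas as pd

    rows = []
    for sink in sinks:
        paths = enumerate_directed_paths(fit.model, source, sink, max_length)
        if not include_direct:
            paths = [p for p in paths if len(p.nodes) > 2]
        elig, inelig = eligible_pathways(fit, paths, alpha)
        for path in elig:
            eff = indirect_effect(fit, path)
            rows.append(eff.to_dict())
        for path, failing in inelig:
            eff = indirect_effect(fit, path, eligible=False, failing_edge=failing)
            d = eff.to_dict()
            rows.append(d)
    return pd.DataFrame(rows)
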
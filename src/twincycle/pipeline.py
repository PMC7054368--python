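"""End-to-end orchestration: cohort table in, report bundle out.

``run_pipeline`` drives the full analysis for one or more models on one
cohort table (a CSV on disk or a synthetic cohort spec): stratified
rank-normal transform, residualisation, pairwise correlations, covariance
construction, ML fit with fit indices, the variable-randomised null test and
the mediation table.  All artefacts are written under an output directory
and tied together by a JSON manifest that echoes the configuration and
seeds, so identical configurations reproduce byte-identical manifests.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fit_indices import baseline_model_fit, compute_fit_indices
from .mediation import mediation_table
from .null_randomisation import randomized_null_distribution
from .path_model import PathModel, builtin_model, parse_model_spec
from .preprocess import (
    covariance_input,
    pairwise_correlations,
    rank_inverse_normal,
    residualize,
)
from .sem_fit import fit_model
from .synthetic import SyntheticCohortSpec, generate_cohort


class ConfigError(ValueError):
    pass


#: Default covariates removed by residual regression.
DEFAULT_COVARIATES = ["age", "centre", "energy", "carbohydrate", "fat", "protein"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` and ``synthetic`` must be given.
    ``column_map`` renames CSV columns to model node / covariate names
    (``{csv_name: node_name}``); superfluous for synthetic cohorts, which
    already use node names.
    """

    output_dir: str | Path = "results/run"
    input_csv: str | Path | None = None
    synthetic: SyntheticCohortSpec | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    models: list[str] = field(default_factory=lambda: ["TC", "TC-PA"])
    offset: float = 3.0 / 8.0
    strata_columns: list[str] | None = None
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    n_iter: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    mediation_source: str = "PA"
    mediation_sinks: list[str] = field(default_factory=lambda: ["FG", "PG"])
    write_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_csv and synthetic must be set")
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")

    def echo(self) -> dict:
        d = {
            "input_csv": str(self.input_csv) if self.input_csv else None,
            "synthetic": None,
            "column_map": dict(self.column_map),
            "models": list(self.models),
            "offset": self.offset,
            "strata_columns": self.strata_columns,
            "covariates": list(self.covariates),
            "n_iter": self.n_iter,
            "seed": self.seed,
            "alpha": self.alpha,
            "mediation_source": self.mediation_source,
            "mediation_sinks": list(self.mediation_sinks),
        }
        if self.synthetic is not None:
            d["synthetic"] = {
                "cohort": self.synthetic.cohort,
                "model_name": self.synthetic.model_name,
                "n": self.synthetic.n,
                "seed": self.synthetic.seed,
                "coefficients": dict(self.synthetic.coefficients),
                "confounder_effects": dict(self.synthetic.confounder_effects),
            }
        return d


def _resolve_model(name: str) -> PathModel:
    if name.upper().replace("_", "-") in ("TC", "TC-PA"):
        return builtin_model(name)
    path = Path(name)
    if path.exists():
        return parse_model_spec(path.read_text())
    raise ConfigError(f"model {name!r} is neither a built-in name nor a spec file")


def load_participant_table(config: RunConfig) -> pd.DataFrame:
    if config.synthetic is not None:
        return generate_cohort(config.synthetic)
    table = pd.read_csv(config.input_csv)
    if config.column_map:
        missing = [c for c in config.column_map if c not in table.columns]
        if missing:
            raise ConfigError(f"columns named in column_map absent from CSV: {missing}")
        table = table.rename(columns=config.column_map)
    return table


def preprocess_cohort(
    table: pd.DataFrame,
    nodes: list[str],
    config: RunConfig,
) -> pd.DataFrame:
    """Stratified rank-normal transform then residualisation of the node
    columns; returns the analysis-ready table of residuals."""
    missing = [n for n in nodes if n not in table.columns]
    if missing:
        raise ConfigError(f"cohort table lacks model variables: {missing}")
    strata_cols = config.strata_columns
    if strata_cols is None:
        strata_cols = ["sex"]
        cohort_label = table.get("cohort")
        if cohort_label is not None and (np.asarray(cohort_label) == 2).any():
            if "treatment" in table.columns:
                strata_cols = ["sex", "treatment"]
    strata = table[strata_cols].astype(str).agg("|".join, axis=1).to_numpy()

    transformed = table.copy()
    for node in nodes:
        transformed[node] = rank_inverse_normal(
            table[node].to_numpy(dtype=float), strata, offset=config.offset
        )
    covs = [c for c in config.covariates if c in table.columns]
    return residualize(transformed, nodes, covs)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = load_participant_table(config)
    manifest: dict = {"config": config.echo(), "models": {}}

    for model_name in config.models:
        model = _resolve_model(model_name)
        analysis = preprocess_cohort(table, model.nodes, config)
        corr = pairwise_correlations(analysis)
        data = covariance_input(analysis, model.nodes)

        fit = fit_model(model, data, compute_se=True, seed=config.seed)
        indices = compute_fit_indices(fit, baseline_model_fit(data))
        null = randomized_null_distribution(
            model, data, n_iter=config.n_iter, seed=config.seed,
            observed_chi2=fit.chi2,
        )

        stem = model.name.lower().replace("-", "_")
        analysis.to_csv(out_dir / f"{stem}_analysis_table.csv", index=False)
        corr.to_csv(out_dir / f"{stem}_correlations.csv")
        fit.to_table().to_csv(out_dir / f"{stem}_edges.csv", index=False)
        np.savetxt(out_dir / f"{stem}_null_chi2.csv", null.chi2_null,
                   header="chi2", comments="")

        entry = {
            "n": data.n,
            "chi2": fit.chi2,
            "df": fit.df,
            "fit_indices": indices.to_dict(),
            "null": null.to_dict(),
            "heywood": fit.heywood,
        }
        if config.mediation_source in model.nodes:
            med = mediation_table(
                fit, config.mediation_source, config.mediation_sinks,
                alpha=config.alpha,
            )
            med.to_csv(out_dir / f"{stem}_mediation.csv", index=False)
            entry["n_mediation_paths"] = int(len(med))
            entry["n_eligible_paths"] = (
                int(med["eligible"].sum()) if len(med) else 0
            )
        if config.write_plots:
            from .null_randomisation import plot_null_density

            ax = plot_null_density(null)
            ax.figure.savefig(out_dir / f"{stem}_null_density.png", dpi=150)
            (out_dir / f"{stem}_model.dot").write_text(model.to_dot())
        manifest["models"][model.name] = entry

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    manifest_path = out_dir / "manifest.json"
    manifest_for_disk = {k: v for k, v in manifest.items() if k != "elapsed_seconds"}
    manifest_path.write_text(json.dumps(manifest_for_disk, indent=2, sort_keys=True))
    return manifest
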
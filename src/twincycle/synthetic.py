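"""Synthetic cohort generation from a linear (possibly cyclic) structural system.

The original cohorts are access-restricted, so every downstream stage is
exercised on simulated participants whose variables obey the same class of
model the pipeline fits: standardized node scores are drawn from
``y = (I - B)^-1 zeta`` with the published standardized edge coefficients as
the generating ``B`` and disturbance variances solved so that every node has
unit implied variance (making the published standardized estimates directly
usable as generating truths).  Confounders (age, study centre, dietary
intake) are drawn independently of the structural disturbances and added
linearly, strata (sex; treatment group in the diabetes cohort) are attached,
and each node is rescaled to the published marginal mean/SD of its raw
variable, yielding a participant table on the measurement scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference_estimates as ref
from .path_model import PathModel, builtin_model
from .sem_fit import SingularSystemError, implied_covariance


class SimulationError(ValueError):
    pass


def structural_b_matrix(model: PathModel, coefficients: dict[str, float]) -> np.ndarray:
    """B matrix (entry [target, source] per edge) from a label -> value map."""
    p = model.n_nodes
    idx = {n: i for i, n in enumerate(model.nodes)}
    B = np.zeros((p, p))
    for e in model.edges:
        if e.label not in coefficients:
            raise SimulationError(f"no coefficient supplied for edge {e.label!r}")
        B[idx[e.target], idx[e.source]] = coefficients[e.label]
    return B


def unit_variance_disturbances(B: np.ndarray) -> np.ndarray:
    """Disturbance variances giving every node unit implied variance.

    With ``A = (I - B)^-1`` the implied variance of node i is
    ``sum_k A[i, k]^2 psi_k``; setting all implied variances to 1 is the
    linear system ``(A ∘ A) psi = 1``, solved directly.
    """
    p = B.shape[0]
    ImB = np.eye(p) - B
    if abs(np.linalg.det(ImB)) < 1e-12:
        raise SingularSystemError("I - B is singular")
    A = np.linalg.inv(ImB)
    psi = np.linalg.solve(A**2, np.ones(p))
    if np.any(psi <= 0):
        raise SimulationError(
            "no positive disturbance variances give unit implied variances "
            "for this B; weaken the coefficients"
        )
    return psi


def simulate_structural_system(
    B: np.ndarray,
    psi: np.ndarray,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` rows of ``y = (I - B)^-1 zeta``, zeta ~ N(0, diag(psi)).

    The population covariance of the output equals
    ``(I - B)^-1 Psi (I - B)^-T``.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise SimulationError("disturbance variances must be positive")
    p = B.shape[0]
    ImB = np.eye(p) - B
    if abs(np.linalg.det(ImB)) < 1e-12:
        raise SingularSystemError("I - B is singular; the system has no reduced form")
    rng = np.random.default_rng(seed)
    zeta = rng.normal(size=(n, p)) * np.sqrt(psi)
    A = np.linalg.inv(ImB)
    return zeta @ A.T


@dataclass
class SyntheticCohortSpec:
    """Configuration of one synthetic cohort.

    Defaults emulate the published study conditions: generating coefficients
    are the published standardized edge estimates for the chosen model and
    cohort, disturbance variances give unit implied node variances, and raw
    marginals match the published cohort characteristics.  Confounder effect
    sizes are on the standardized scale (SD of node per SD of confounder, or
    per category shift for centre).
    """

    cohort: int = 1
    model_name: str = "TC-PA"
    n: int = 725
    seed: int = 0
    coefficients: dict[str, float] | None = None
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.10,
            "centre": 0.10,
            "energy": 0.05,
            "carbohydrate": 0.03,
            "fat": 0.03,
            "protein": 0.03,
        }
    )
    n_centres: int = 4
    marginals: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.cohort not in (1, 2):
            raise SimulationError("cohort label must be 1 or 2")
        if self.n < 2:
            raise SimulationError("n must be at least 2")
        if self.n < 50:
            warnings.warn(
                f"n = {self.n} is far below a realistic cohort size",
                RuntimeWarning,
                stacklevel=2,
            )
        if self.coefficients is None:
            self.coefficients = dict(ref.EDGE_ESTIMATES[(self.model_name, self.cohort)])
            self.coefficients = {
                k: v.beta if hasattr(v, "beta") else float(v)
                for k, v in self.coefficients.items()
            }
        if self.marginals is None:
            self.marginals = dict(ref.MARGINALS[self.cohort])

    @property
    def model(self) -> PathModel:
        return builtin_model(self.model_name)


#: Covariate column names the generator emits alongside the node variables.
COVARIATE_COLUMNS = [
    "age", "sex", "centre", "treatment", "energy", "carbohydrate", "fat",
    "protein", "cohort",
]


def attach_confounders(scores: np.ndarray, spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Add confounders and strata to standardized node scores and rescale to
    the raw measurement scale.

    Confounders are drawn independently of the structural disturbances and
    enter additively on the standardized scale; afterwards each node column
    is rescaled to its published marginal mean/SD, producing the raw-scale
    participant table the preprocessing stage expects.
    """
    model = spec.model
    n = scores.shape[0]
    if scores.shape[1] != model.n_nodes:
        raise SimulationError("scores do not match the model's node count")
    for k, (m, s) in spec.marginals.items():
        if not (np.isfinite(m) and np.isfinite(s) and s > 0):
            raise SimulationError(f"non-finite calibration target for {k!r}")

    demo = ref.DEMOGRAPHICS[spec.cohort]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20 + 7]))
    age = rng.normal(demo["age_mean"], demo["age_sd"], size=n)
    sex = np.where(rng.random(n) < demo["male_fraction"], "male", "female")
    centre = rng.integers(0, spec.n_centres, size=n)
    if spec.cohort == 2:
        treatment = np.where(rng.random(n) < 0.5, "metformin_lifestyle", "lifestyle")
    else:
        treatment = np.repeat("lifestyle", n)
    # dietary intakes: energy in kJ/day, macronutrients in g/day, log-normal-ish
    energy = rng.normal(9000.0, 2000.0, size=n).clip(min=3000.0)
    carbohydrate = rng.normal(230.0, 60.0, size=n).clip(min=50.0)
    fat = rng.normal(85.0, 25.0, size=n).clip(min=15.0)
    protein = rng.normal(90.0, 20.0, size=n).clip(min=20.0)

    eff = spec.confounder_effects
    z_age = (age - demo["age_mean"]) / demo["age_sd"]
    z_energy = (energy - energy.mean()) / energy.std()
    z_carb = (carbohydrate - carbohydrate.mean()) / carbohydrate.std()
    z_fat = (fat - fat.mean()) / fat.std()
    z_prot = (protein - protein.mean()) / protein.std()
    centre_shift = np.linspace(-1.0, 1.0, spec.n_centres)[centre]

    confound = (
        eff.get("age", 0.0) * z_age
        + eff.get("centre", 0.0) * centre_shift
        + eff.get("energy", 0.0) * z_energy
        + eff.get("carbohydrate", 0.0) * z_carb
        + eff.get("fat", 0.0) * z_fat
        + eff.get("protein", 0.0) * z_prot
    )

    table = pd.DataFrame(index=pd.RangeIndex(n, name="participant"))
    for j, node in enumerate(model.nodes):
        z = scores[:, j] + confound
        mean, sd = spec.marginals[node]
        table[node] = mean + sd * (z - z.mean()) / z.std()
    table["age"] = age
    table["sex"] = sex
    table["centre"] = pd.Categorical([f"centre_{c}" for c in centre])
    table["treatment"] = pd.Categorical(treatment)
    table["energy"] = energy
    table["carbohydrate"] = carbohydrate
    table["fat"] = fat
    table["protein"] = protein
    table["cohort"] = spec.cohort
    return table


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Full synthetic participant table: structural scores + confounders,
    on the raw measurement scale.  Deterministic for a given seed."""
    model = spec.model
    B = structural_b_matrix(model, spec.coefficients)
    psi = unit_variance_disturbances(B)
    if spec.n <= model.n_free_parameters:
        warnings.warn(
            f"n = {spec.n} does not exceed the model's free-parameter count "
            f"({model.n_free_parameters}); fits will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    scores = simulate_structural_system(B, psi, spec.n, seed=spec.seed)
    return attach_confounders(scores, spec)


def generating_truth(spec: SyntheticCohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(B, psi, population covariance) of the cohort's generating structural system."""
    B = structural_b_matrix(spec.model, spec.coefficients)
    psi = unit_variance_disturbances(B)
    return B, psi, implied_covariance(B, psi)
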
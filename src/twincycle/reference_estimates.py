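"""Published reference estimates for the twin-cycle structural models.

The IMI DIRECT analysis of the twin-cycle (TC) and twin-cycle plus physical
activity (TC-PA) path models reported standardized edge coefficients, their
standard errors and p values for two cohorts: cohort 1 (normoglycaemia /
prediabetes) and cohort 2 (recently diagnosed type 2 diabetes).  The raw
participant data are access-restricted, but the printed estimates are public
and serve two roles here:

* generating truths for the synthetic cohort simulator (the standardized
  coefficients double as a structural B matrix on the standardized scale);
* operands for the desk-reproducible worked examples — each published pathway
  (mediation) estimate equals the product of the published edge estimates
  along its path, up to two-decimal input rounding.

Node abbreviations (all manifest variables, measured per participant):

====  =============================================================
PA    physical activity intensity (mean wrist hpfVM, m*g*)
IS    insulin sensitivity (2 h OGIS, ml min^-1 m^-2)
LF    liver fat (%)
FI    fasting insulin secretion rate (pmol min^-1 m^-2)
FG    fasting plasma glucose (mmol/l)
PG    2 h glucose (mmol/l)
TG    fasting triacylglycerol (mmol/l)
PF    pancreatic fat (%)
GS    glucose sensitivity (pmol min^-1 m^-2 (mmol/l)^-1)
====  =============================================================
"""

from __future__ import annotations

from typing import NamedTuple


class EdgeEstimate(NamedTuple):
    """A published standardized edge coefficient with its SE and p value."""

    beta: float
    se: float
    p: float


#: Published standardized edge estimates, keyed (model, cohort) -> {edge label: estimate}.
#: Edge labels follow the original diagrams (is1..is2, lf1..lf2, fi1..fi3, fg1..fg3,
#: tg1..tg3, pf1..pf2, gs1..gs3, pg1..pg3).
EDGE_ESTIMATES: dict[tuple[str, int], dict[str, EdgeEstimate]] = {
    ("TC", 1): {
        "is1": EdgeEstimate(-0.23, 0.04, 1e-4),
        "lf1": EdgeEstimate(0.41, 0.04, 1e-4),
        "fi1": EdgeEstimate(-0.06, 0.03, 0.05),
        "fi2": EdgeEstimate(-0.70, 0.03, 1e-4),
        "fg1": EdgeEstimate(-0.67, 0.03, 1e-4),
        "fg2": EdgeEstimate(-0.26, 0.03, 1e-4),
        "tg1": EdgeEstimate(-0.31, 0.03, 1e-4),
        "tg2": EdgeEstimate(0.22, 0.03, 1e-4),
        "pf1": EdgeEstimate(0.14, 0.03, 1e-4),
        "gs1": EdgeEstimate(-0.05, 0.04, 0.185),
        "gs2": EdgeEstimate(-0.21, 0.03, 1e-4),
        "pg1": EdgeEstimate(-0.58, 0.03, 1e-4),
        "pg2": EdgeEstimate(-0.17, 0.03, 1e-4),
    },
    ("TC", 2): {
        "is1": EdgeEstimate(-0.11, 0.06, 0.09),
        "lf1": EdgeEstimate(0.44, 0.05, 1e-4),
        "fi1": EdgeEstimate(-0.25, 0.06, 1e-4),
        "fi2": EdgeEstimate(-0.70, 0.06, 1e-4),
        "fg1": EdgeEstimate(-0.73, 0.03, 1e-4),
        "fg2": EdgeEstimate(-0.31, 0.03, 1e-4),
        "tg1": EdgeEstimate(-0.34, 0.05, 1e-4),
        "tg2": EdgeEstimate(0.13, 0.05, 0.006),
        "pf1": EdgeEstimate(0.01, 0.05, 0.886),
        "gs1": EdgeEstimate(0.005, 0.05, 0.967),
        "gs2": EdgeEstimate(0.02, 0.05, 0.63),
        "pg1": EdgeEstimate(-0.67, 0.03, 1e-4),
        "pg2": EdgeEstimate(-0.38, 0.03, 1e-4),
    },
    ("TC-PA", 1): {
        "is2": EdgeEstimate(0.30, 0.04, 1e-4),
        "is1": EdgeEstimate(-0.20, 0.04, 1e-4),
        "lf2": EdgeEstimate(-0.04, 0.04, 0.234),
        "lf1": EdgeEstimate(0.41, 0.04, 1e-4),
        "fi3": EdgeEstimate(-0.12, 0.03, 1e-4),
        "fi1": EdgeEstimate(-0.04, 0.03, 0.265),
        "fi2": EdgeEstimate(-0.64, 0.04, 1e-4),
        "fg3": EdgeEstimate(0.11, 0.03, 0.001),
        "fg1": EdgeEstimate(-0.70, 0.03, 1e-4),
        "fg2": EdgeEstimate(-0.26, 0.03, 1e-4),
        "tg3": EdgeEstimate(-0.13, 0.04, 1e-4),
        "tg1": EdgeEstimate(-0.26, 0.04, 1e-4),
        "tg2": EdgeEstimate(0.22, 0.04, 1e-4),
        "pf2": EdgeEstimate(-0.06, 0.03, 0.067),
        "pf1": EdgeEstimate(0.14, 0.03, 1e-4),
        "gs3": EdgeEstimate(-0.05, 0.04, 0.212),
        "gs1": EdgeEstimate(-0.05, 0.05, 0.314),
        "gs2": EdgeEstimate(-0.18, 0.04, 1e-4),
        "pg3": EdgeEstimate(-0.04, 0.03, 0.194),
        "pg1": EdgeEstimate(-0.56, 0.03, 1e-4),
        "pg2": EdgeEstimate(-0.17, 0.03, 1e-4),
    },
    ("TC-PA", 2): {
        "is2": EdgeEstimate(0.21, 0.05, 1e-4),
        "is1": EdgeEstimate(-0.12, 0.07, 0.065),
        "lf2": EdgeEstimate(-0.04, 0.05, 0.447),
        "lf1": EdgeEstimate(0.44, 0.05, 1e-4),
        "fi3": EdgeEstimate(-0.16, 0.05, 0.001),
        "fi1": EdgeEstimate(-0.23, 0.07, 1e-4),
        "fi2": EdgeEstimate(-0.64, 0.07, 1e-4),
        "fg3": EdgeEstimate(0.06, 0.03, 0.061),
        "fg1": EdgeEstimate(-0.73, 0.03, 1e-4),
        "fg2": EdgeEstimate(-0.28, 0.03, 1e-4),
        "tg3": EdgeEstimate(-0.13, 0.05, 0.012),
        "tg1": EdgeEstimate(-0.30, 0.05, 1e-4),
        "tg2": EdgeEstimate(0.16, 0.05, 0.002),
        "pf2": EdgeEstimate(-0.01, 0.06, 0.809),
        "pf1": EdgeEstimate(-0.01, 0.05, 0.819),
        "gs3": EdgeEstimate(-0.12, 0.06, 0.032),
        "gs1": EdgeEstimate(0.01, 0.05, 0.835),
        "gs2": EdgeEstimate(0.02, 0.05, 0.696),
        "pg3": EdgeEstimate(-0.05, 0.04, 0.162),
        "pg1": EdgeEstimate(-0.67, 0.03, 1e-4),
        "pg2": EdgeEstimate(-0.39, 0.03, 1e-4),
    },
}


class PathwayEstimate(NamedTuple):
    """A published pathway (mediation) effect estimate from the TC-PA model."""

    outcome: str
    path: tuple[str, ...]
    beta: float
    se: float
    p: float
    cohort: int


#: Published pathway (coefficient-product) estimates of physical activity on
#: glycaemic control, per cohort.  Pathways whose edges were not all
#: individually significant in a cohort were not reported for that cohort.
PATHWAY_ESTIMATES: list[PathwayEstimate] = [
    PathwayEstimate("FG", ("PA", "IS", "FG"), -0.212, 0.026, 1e-4, 1),
    PathwayEstimate("FG", ("PA", "IS", "FG"), -0.153, 0.039, 1e-4, 2),
    PathwayEstimate("PG", ("PA", "IS", "PG"), -0.171, 0.022, 1e-4, 1),
    PathwayEstimate("PG", ("PA", "IS", "PG"), -0.140, 0.036, 1e-4, 2),
    PathwayEstimate("FG", ("PA", "IS", "GS", "FG"), 0.015, 0.004, 1e-4, 1),
    PathwayEstimate("PG", ("PA", "IS", "GS", "PG"), 0.009, 0.003, 0.001, 1),
    PathwayEstimate("FG", ("PA", "FI", "LF", "IS", "FG"), -0.007, 0.002, 0.002, 1),
    PathwayEstimate("PG", ("PA", "FI", "LF", "IS", "PG"), -0.006, 0.002, 0.002, 1),
    PathwayEstimate("FG", ("PA", "GS", "FG"), 0.033, 0.016, 0.037, 2),
    PathwayEstimate("PG", ("PA", "GS", "PG"), 0.045, 0.022, 0.04, 2),
]


#: Published marginal mean (SD) of each raw variable per cohort, from the
#: TC-PA complete-case subcohorts (cohort 1 n = 725, cohort 2 n = 361).
#: PA has no published marginal; the default emulates typical wrist hpfVM.
MARGINALS: dict[int, dict[str, tuple[float, float]]] = {
    1: {
        "FG": (5.8, 0.5),
        "PG": (6.0, 1.7),
        "TG": (1.4, 0.7),
        "FI": (106.0, 41.0),
        "GS": (107.0, 50.0),
        "IS": (374.0, 56.0),
        "LF": (5.0, 4.7),
        "PF": (13.6, 9.1),
        "PA": (32.0, 15.0),
    },
    2: {
        "FG": (7.0, 1.4),
        "PG": (8.5, 2.8),
        "TG": (1.5, 0.9),
        "FI": (136.0, 50.0),
        "GS": (89.0, 56.0),
        "IS": (302.0, 70.0),
        "LF": (8.9, 7.4),
        "PF": (11.7, 6.9),
        "PA": (32.0, 15.0),
    },
}

#: Published demographic summaries used by the cohort generator.
DEMOGRAPHICS: dict[int, dict[str, float]] = {
    1: {"age_mean": 60.6, "age_sd": 6.3, "male_fraction": 0.83},
    2: {"age_mean": 61.7, "age_sd": 8.4, "male_fraction": 0.60},
}

#: Published model-fit statistics (observed chi-square, mean null chi-square,
#: empirical p against a 10,000-iteration variable-randomised null), keyed
#: (model, cohort).  Not reproducible without the restricted data; retained
#: for context in reports.
FIT_STATISTICS: dict[tuple[str, int], dict[str, float]] = {
    ("TC", 1): {"chi2": 242.0, "null_mean_chi2": 1005.0, "empirical_p": 0.004},
    ("TC", 2): {"chi2": 63.0, "null_mean_chi2": 587.0, "empirical_p": 0.001},
    ("TC-PA", 1): {"chi2": 180.0, "null_mean_chi2": 605.0, "empirical_p": 0.041},
    ("TC-PA", 2): {"chi2": 60.0, "null_mean_chi2": 369.0, "empirical_p": 0.008},
}

#: Complete-case sample sizes per (model, cohort).
SAMPLE_SIZES: dict[tuple[str, int], int] = {
    ("TC", 1): 920,
    ("TC", 2): 435,
    ("TC-PA", 1): 725,
    ("TC-PA", 2): 361,
}
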
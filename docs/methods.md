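# Methods

## The model

The twin-cycle (TC) hypothesis describes impaired glycaemic control through
two interacting cycles of ectopic fat accumulation: a liver cycle (liver
fat, insulin sensitivity, fasting insulin secretion, fasting glucose) and a
pancreas cycle (triacylglycerol, pancreatic fat, beta-cell glucose
sensitivity, 2 h glucose).  The TC-PA extension adds habitual physical
activity (PA) as an exogenous node with a direct edge into every metabolic
node, so that the extent to which PA's association with glycaemic control is
mediated by twin-cycle variables can be quantified.

Both models are manifest-variable path models: a simultaneous linear system

```
y = B y + ζ,   ζ ~ N(0, Ψ),   Ψ diagonal
```

over observed variables only.  The system is non-recursive — the TC wiring
contains the directed cycle IS → FI → LF → IS — so everything is formulated
through the reduced form `y = (I − B)⁻¹ ζ` and its implied covariance

```
Σ(θ) = (I − B)⁻¹ Ψ (I − B)⁻ᵀ
```

rather than by topological substitution.  Validity of a candidate B is
invertibility of (I − B), checked at every optimisation step.

Disturbance covariances are fixed at zero (diagonal Ψ): the model diagrams
declare no correlated errors.  The exogenous PA node follows the fixed-x
convention: its variance is fixed to the sample value, which reproduces that
moment exactly.  Consequently df = p(p+1)/2 − q_free − (#fixed exogenous
variances): 36 − 21 = 15 for TC and 45 − 29 − 1 = 15 for TC-PA.  The
convention is switchable (`free_exogenous_variance`) for sensitivity checks.

## Preprocessing

Continuous variables are rank-inverse-normal transformed within strata (sex;
sex × treatment group in the diabetes cohort) with the Blom offset c = 3/8:
`Φ⁻¹((r − c)/(n − 2c + 1))`, average ranks for ties.  The offset is a
parameter; Blom is the default because it is the most common convention and
its scores have mean 0 and SD ≈ 1 within each stratum.  Confounders (age,
study centre, total energy and macronutrient intakes) are then removed by
two-step residual regression: OLS of each transformed variable on an
intercept plus the covariates (categoricals dummy-coded against a reference
level, exactly collinear columns pruned), keeping the residuals.  Residuals
are not re-standardised afterwards — the standardized SEM solution handles
scale, and re-scaling would alter raw Wald SEs without changing standardized
estimates.  Missing data are handled by complete-case (listwise) deletion at
covariance construction, not by imputation.  Sex enters through
stratification only, not additionally as a regression covariate.

The sample covariance uses the N − 1 denominator and is checked for positive
definiteness before fitting.

## Estimation

`F_ML = ln|Σ| − ln|S| + tr(S Σ⁻¹) − p` is minimised over the free entries of
(B, Ψ) by L-BFGS-B with an analytic gradient (with A = (I − B)⁻¹ and
M = Σ⁻¹ − Σ⁻¹SΣ⁻¹: ∂F/∂B[t,s] = 2(ΣMA)[s,t], ∂F/∂Ψ[k,k] = (AᵀMA)[k,k]).
Start values are zero path coefficients and half the sample variances;
non-convergence triggers up to 10 seeded jittered restarts.  Disturbance
variances are bounded below at 1e-6; a solution pinned at that bound is
flagged as a Heywood case.  Trial points with singular (I − B) or non-PD Σ
return a large objective value so the line search retreats.  Convergence
requires a projected-gradient norm below 1e-4 (the optimiser's own tolerance
is 1e-8).

The fit statistic is χ² = (N − 1)·F_ML (Wishart scaling; N is switchable).
Standard errors come from the numerically differentiated Hessian of F_ML
(central differences of the analytic gradient, relative step 1e-5):
ACOV = (2/(N−1))·H⁻¹, SE = √diag ACOV, two-sided normal Wald p-values with
no multiple-testing adjustment.  Whether an observed- or expected-information
matrix is preferable is unresolved for this design; the Hessian route is the
default because it is testable by bootstrap, and the SE-calibration test
(empirical SD of estimates vs mean reported SE over replicates) covers it.

Standardized coefficients are `β_std = b·σ_source/σ_target` with σ from
diag Σ(θ̂); they are invariant to positive rescaling of any observed column.

## Fit indices

CFI and TLI use the independence baseline (Σ_B = diag S, df_B = p(p−1)/2,
with the closed form χ²_B = (N−1)(ln|diag S| − ln|S|)); RMSEA uses the (N−1)
denominator consistent with the χ² scaling.  The indices are reported but
carry no decision role; model adequacy is judged by the randomised-null
test.

## Variable-randomised null test

Each iteration draws a uniform random permutation of the variable-to-node
assignment (identity excluded, duplicates across iterations allowed — i.e.
sampling with replacement from the permutation space), permutes the rows and
columns of S accordingly, refits the identical structure, and records χ².
All nodes are permuted, including the exogenous PA node; both choices
(identity inclusion, exogenous exclusion) are parameters because the
procedure's original description does not pin them down.  Non-convergent
null fits are dropped and counted; a convergence rate below 50% is an error.
The default iteration count is 10,000.

Summaries: the add-one empirical quantile
`p = (1 + #{χ²_null ≤ χ²_obs})/(n + 1)` (never exactly zero), and a
one-sample t test of the null sample against the observed value with
alternative "null mean greater than observed".

## Mediation

Pathways are simple directed paths (no node revisited).  Eligibility follows
the Baron–Kenny-style screen: every traversed edge must be individually
significant at two-sided α = 0.05; ineligible paths report their first
failing edge.  The indirect effect is the product of fitted standardized
coefficients along the path.  Its delta-method variance is gᵀ·ACOV_path·g
with gᵢ = ∏_{j≠i} βⱼ, where ACOV_path is the joint covariance of the path's
edge coefficients mapped to the standardized scale by the fixed ratios
σ_source/σ_target (the variability of the implied SDs themselves is ignored
in this linearisation — a deliberate simplification validated against a full
parametric bootstrap, which agrees within a few percent at these sample
sizes).  The Sobel independence approximation is available for two-edge
paths.  Mediation operates on the standardized scale by default.

## Synthetic cohorts

The original participant-level data are access-restricted, so the generator
emulates cohorts with the statistical structure the analysis assumes:

- **Structural scores.**  Node scores are drawn from the linear system with
  the published standardized edge estimates (per model and cohort) as the
  generating B.  Disturbance variances solve the linear system
  `(A∘A)ψ = 1` (A = (I−B)⁻¹), giving every node unit implied variance so
  that published standardized estimates are directly usable as generating
  coefficients.
- **Confounders.**  Age (per-cohort published mean/SD), a 4-level study
  centre with linearly spaced shifts, and dietary intakes (energy ~9,000 kJ,
  carbohydrate ~230 g, fat ~85 g, protein ~90 g per day) are drawn
  independently of the structural disturbances and added linearly on the
  standardized scale (defaults: 0.10 SD/SD for age and centre, 0.03–0.05 for
  diet — modest confounding that residualisation must remove).  Strata: sex
  (83% / 60% male in cohorts 1 / 2) and, in cohort 2, a 50/50
  lifestyle vs metformin + lifestyle treatment split.
- **Calibration.**  Each node column is rescaled to the published marginal
  mean (SD) for its cohort — e.g. fasting glucose 5.8 (0.5) mmol/l in
  cohort 1, 7.0 (1.4) in cohort 2.  PA has no published marginal; the
  default 32 (15) m*g* emulates typical adult wrist-acceleration (hpfVM)
  magnitudes.

What the generator does **not** emulate: non-normal measurement error,
skewed raw distributions (liver fat is strongly right-skewed in reality; the
rank-normal transform makes this immaterial downstream but raw-scale
realism is limited), structured missingness, correlated disturbances, or
any within-day accelerometer/OGTT signal structure.  Because the generator's
diagonal-Ψ assumption matches the fitted model by construction, passing
tests demonstrate correctness of the machinery and calibration of the
statistics under the model — not robustness to the misspecification real
data would carry.

## Problem sizes in the tests and acceptance script

Simulation-based checks use the study's own complete-case sample sizes
(n = 920/725 for cohort 1, 435/361 for cohort 2): χ² calibration runs 500
replicates at n = 920; parameter/SE recovery 200 replicates at n = 1,000;
the null-test property 20 cohorts × 1,000 null iterations; the bootstrap
cross-check 2,000 draws.  The analysis drivers use 2,000 null iterations
(empirical-p resolution 1/2,001; the library default remains 10,000).
Replicate seeds are spawned from a single parent generator.

## Known limitations

- Only ML on covariance matrices: no GLS/WLS/robust estimators, no mean
  structure, no latent variables, no FIML for missing data.
- RMSEA confidence intervals and close-fit tests are not computed.
- The null-test and mediation procedures assume a converged, identified
  fit; near-unidentified structures (smallest Jacobian singular values near
  zero) will surface as optimisation or Heywood warnings rather than being
  detected explicitly.
- The real-data fit statistics of the original cohorts cannot be reproduced
  without access to the restricted data; all quantitative checks are against
  published coefficient tables (desk-reproducible products) or synthetic
  truths.
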
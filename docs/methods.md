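# Methods

## Compositional geometry

A composition is a vector of D strictly positive parts carrying relative
information only; all statistics are invariant to rescaling a subject's row.
Closure normalizes to κ = 100 (percent).  We use:

* **clr** (centred log-ratio): `clr(x)_i = ln(x_i / g(x))`, `g` the geometric
  mean of the row.  Sums to zero; the natural space for coefficient vectors.
* **Pivot ilr coordinates**: for part order `(o₁, …, o_D)`, coordinate *i* is
  `√((D−i)/(D−i+1)) · ln(x_{o_i} / gmean(x_{o_{i+1}}, …, x_{o_D}))`.  The
  contrast matrix `V` (D × D−1) has orthonormal, zero-sum columns, so
  `z = Vᵀ ln x = Vᵀ clr x` and the map is an isometry of Aitchison geometry.
  Sign convention: a positive first coordinate means more of the leading part
  relative to the geometric mean of the rest.
* **Variation matrix**: `T_ij = var(ln(x_i/x_j))`, computed from the
  log-part covariance (`T_ij = C_ii + C_jj − 2C_ij`); sample variances use
  divisor N−1 throughout the package, matching the mean ± SD reporting of
  the descriptive tables.
* **Per-part compositional geometric means** of closed rows are reported
  *unclosed*: with any dispersion they sum strictly below κ (the reference
  values 36.1 + 38.9 + 20.0 + 4.2 = 99.2 illustrate this), and re-closing
  them would misstate the centre.

Zero or negative parts are rejected at ingestion rather than imputed; the
four fatty-acid classes are never zero in plausible diets, and multiplicative
zero-replacement is deliberately out of scope.

## Regression models

**Compositional OLS** (`CompositionalOLS`): outcome (ln-transformed for
LDL-C, HDL-C, AST, ALT, GGT, which are right-skewed) on the D−1 pivot
coordinates plus confounders, refitted once per rotation (default order SFA,
MUFA, omega-6, omega-3; arbitrary orders are accepted).  Confounder sets:
age, sex, energy (kcal), carbohydrate (%E), sodium (mg/1000 kcal), physical
activity, sleep, screen time, single parent, siblings — plus zBMI for all
non-anthropometric outcomes.  Sex is coded 0/1 (female/male); the ordinal
covariates (screen time, siblings) enter as single numeric scores — a
defensible simplification that keeps one coefficient per covariate; dummy
coding can be passed explicitly via the `confounders` argument with
pre-built indicator columns.  The unadjusted R² and F-test p come from the
intercept + coordinates model only.  p-values are two-sided t tests at
residual degrees of freedom; no robust errors, no multiplicity correction
(raw p values are reported, as is conventional for a single pre-specified
exposure family).  Rank-deficient designs fail loudly, naming the collinear
columns.

clr coefficients are assembled from any single rotation as `a = V·b`; they
are rotation-invariant and satisfy `Σa = 0` to numerical precision.  The
first-pivot coefficient of part *j* equals `a_j·√(D/(D−1))`.  The inverse
reconstruction (`clr_coeffs_from_first_pivot`) applies
`a_j = √((D−1)/D)·β_j` to externally reported first-pivot rows and returns
the residual `Σa` as a diagnostic: nonzero residuals flag rounded inputs
(printed 2-decimal coefficient tables leave residuals near 0.01).

**Sensitivity families**: (i) fat %E replacing carbohydrate %E; (ii) all 16
subsets of {energy, protein, fat, carbohydrate} as the macro adjustment,
with rank-deficient variants reported as skipped; (iii) a 7-part
energy-nutrient composition (protein, carbohydrate, the four fatty acids,
fat-other-than-named-FAs) through the same pivot machinery (7 rotations × 6
coordinates), with the macro confounders removed since they now live inside
the composition.

**Substitution models** (`SubstitutionOLS`): outcome on energy, protein %E,
carbohydrate %E, the three non-omitted fatty acids (%E), fat without fatty
acids (fat %E − Σ FA %E), and the same confounders.  The omitted class is
omega-6 for the SFA model and SFA otherwise.  The fat-without-fatty-acids
term is included in *all four* models (one published model description lists
it only for the SFA model; omitting it would break the isocaloric
interpretation) — switchable via `include_fat_other=False`.  When the
covariate span is unchanged by which class is omitted, the coefficient of
the substituted-in class flips sign exactly under the swap; the tests verify
this reparameterization identity.

**Change matrices** (`change_matrix`): δ (default 4) percentage points moved
from a donor to a recipient part around the mean composition; entry =
`a·(clr(x′) − clr(x̄))`, exponentiated for log-scale outcomes.  δ is an
absolute share of the closed total, not a relative fraction of the donor.
Donor parts ≤ δ yield NaN entries listed as undefined; reallocations leaving
a donor below 1 % are flagged as extreme extrapolation (moving 4 points out
of omega-3's 4.2 % leaves 0.2 %).  The reference composition is closed to
100 by default; using the raw 99.2-sum vector of published geometric means
instead shifts ratio entries by < 5×10⁻⁴ (`close_mean=False` exposes this).

## Synthetic cohort generator

The study data are available only on request, so the pipeline is exercised
on synthetic cohorts that emulate the published summary structure:

* **Composition**: clr coordinates are multivariate normal with covariance
  `Σ = −½·G·T·G` (G the centering projector) — the unique row-centred
  covariance whose induced log-ratio variances reproduce the target
  variation matrix exactly.  A variation matrix whose double-centred form
  has a materially negative eigenvalue is rejected as non-realizable.
* **Centre calibration**: geometric means of *closed* draws are proportional
  to `exp(μ)` with a scale factor determined by Σ; a pilot-sample fixed
  point (default 10⁵ draws, tolerance 0.05 percentage points, ≤ 50
  iterations) aligns them with the targets.  With the default targets the
  structural scale factor leaves a ≈ +0.03-point offset on the largest part
  — inside the tolerance, and irreducible given that the targets sum to 99.2
  while the achievable geometric-mean sum under Σ is ≈ 99.28.  Log-ratio
  variances are reproduced exactly in distribution.
* **Diet marginals**: fatty-acid total %E ~ Normal(26.2, 5.1); fat %E =
  FA-total / 0.87 (the published share of fat energy in the four named
  classes); energy ~ Normal(2238, 640); protein, carbohydrate, sodium from
  their reported marginals.  All Gaussians are truncated at ±4 SD (and
  above zero) to guarantee positivity with negligible distortion.
* **Confounders** are drawn independently of the composition (no joint
  distribution is published); `confounder_clr_loadings` injects
  composition–confounder correlation to stress adjustment.  Screen time is
  a 5-level ordinal; siblings 1–3.
* **Outcomes**: `η = intercept + a·clr(x) + γ·confounders + N(0, σ)`, on
  the natural-log scale (then exponentiated) for LDL-C, HDL-C, AST, ALT,
  GGT.  Default `a` vectors are √(3)/2 × the published first-pivot rows.
  Residual SDs reproduce the reported outcome SDs given that the
  composition explains < 1 % of variance (e.g. σ(ln LDL) = 0.21 ≈ 19/86.9);
  intercepts are set analytically so raw-scale means match the reported
  marginals.  Confounder effects default to a few small, plausible values
  (sex/age on anthropometry and blood pressure) — they are not published
  quantities and, being independent of the composition, do not bias
  coefficient recovery.
* A 2 % prevalence of physician-diagnosed excludable disease exercises the
  exclusion rules.  Everything derives from one `numpy` Generator seed;
  identical configs produce byte-identical tables.

What the generator does *not* emulate: questionnaire measurement error,
day-to-day dietary variance, joint diet–lifestyle structure, or any
nonlinear dose–response.  Passing recovery tests therefore demonstrate the
correctness of the estimators under the stated generating model, not the
robustness of the epidemiological findings to real-data complications.

## Filters

Exclusions in order: (1) missing diet/covariate data; (2) implausible
energy — outside [0.5 × EER(PAL 1), 1.5 × EER(PAL 3)], sex-specific
reference energy expenditures for ages 12–14 defaulting to the Japanese DRI
values (male 2300/2900 kcal, female 2150/2700; package defaults, not
measured cohort values); (3) physician-diagnosed disease; (4) LDL-C ≥ 140
mg/dL (inclusive; screening cut-off for possible familial
hyperlipidemia).  Rows are tallied at the first failing rule, matching a
selection-flow diagram; the filter is idempotent.

## Descriptives

Outcome quintiles cut at the 20/40/60/80 empirical percentiles with ties
assigned to the lower category (a documented choice; any convention shifts
only tie groups).  Quintile clr bars: per quintile and part,
`ln(gm_within / gm_overall)`, centred across the five quintiles per part, so
bars sum to zero by construction and a positive bar reads as "relative mean
above the overall mean composition".  Ternary coordinates use the standard
barycentric map after amalgamating (summing) a designated pair of the four
parts; amalgamation commutes with closure.  All four leave-one-out pairings
are emitted since the display does not fix one.

## Problem sizes and numerics

The test suite runs on cohorts of 300–2,500 subjects for model contracts
and 20,000–200,000 for calibration/recovery checks; the acceptance script
uses 200,000 subjects with a 100,000-draw calibration pilot.  Type-I error
of the coordinate t-tests is checked over 1,000 null replicates at N = 500
against a binomial 3-SE band.  Identities are asserted at 1e-9 (rotation
invariance, isometry, reparameterization) or 1e-10 (clr coefficient sum,
prediction finite differences); the change-matrix antisymmetry residual is
second-order in δ and is tested for quadratic decay rather than against an
arbitrary absolute bound.

## Known limitations

Cross-sectional linear models only: no mixed effects, survey weights,
measurement-error correction, imputation, robust/Bayesian CoDA estimators,
zero-replacement, or confidence intervals on change-matrix entries.  The
zBMI input is taken as given (no growth-reference computation).  Printed
2-decimal coefficient tables reconstruct change matrices only to ≈ ±0.003
for ratio entries, and substantially worse for entries involving the
omega-3 column, where the ≈ 2.3 log-ratio shift amplifies coefficient
rounding.
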
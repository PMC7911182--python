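# facoda

Compositional data analysis (CoDA) of dietary fatty-acid composition and
cardiometabolic risk.

## The problem

Dietary fatty acids — saturated (SFA), monounsaturated (MUFA), omega-6 and
omega-3 polyunsaturated (PUFA) — are consumed as a *composition*: eating
relatively more of one necessarily means relatively less of the others.
Classical regressions on absolute intakes, and even isocaloric substitution
models, ignore this mutual dependence.  `facoda` implements the CoDA
approach for a four-part fatty-acid composition against cardiometabolic
outcomes (anthropometry, serum lipids, blood pressure, liver enzymes) in an
adolescent cohort setting, alongside the traditional substitution models for
comparison.  It is aimed at nutritional epidemiologists who want the full
pipeline — Aitchison-geometry primitives, pivot-coordinate regression,
variation matrices, reallocation change matrices — as tested, reusable code.

## The model

Write the closed composition `x = (x_SFA, x_MUFA, x_ω6, x_ω3)`,
`Σ x_j = 100`.  Pivot isometric log-ratio (ilr) coordinates

    z₁ = √((D−1)/D) · ln( x₁ / gmean(x₂, …, x_D) ),   D = 4,

(and the analogous recursion for z₂, z₃) give an orthonormal basis of the
simplex.  For each outcome y (natural-log transformed when right-skewed):

    y = β₀ + β·z₁ + (coefficients on z₂, z₃) + γ·confounders + ε.

Rotating each part into the first pivot position yields one interpretable
coefficient per fatty acid — its effect *relative to the remaining fatty
acids* — while fitted values, R² and the model F test are rotation-invariant.
The clr-space coefficient vector `a = V·b` (with `Σ aⱼ = 0`, and
`a_j = √((D−1)/D)·β_j` from the first-pivot coefficients) feeds the
**change matrix**: for a reallocation of δ = 4 percentage points from part
*j* to part *i* around the mean composition x̄,

    Δη = a · (clr(x′) − clr(x̄)),     x′ = x̄ + δ(eᵢ − eⱼ),

reported as a difference (raw-scale outcomes) or ratio `exp(Δη)` (log-scale
outcomes).

Because the source cohort is not publicly deposited, the package ships a
calibrated **logistic-normal generator**: clr coordinates are Gaussian with
covariance `Σ = −½·G·T·G` (double-centred variation matrix `T`), mean
calibrated so the closed draws reproduce the published per-part geometric
means, with outcomes generated from the published coefficient structure.

## Worked example

```
facoda simulate --n 5485 --seed 0 --out cohort.csv
facoda filter --cohort cohort.csv --out kept.csv --tally-out tally.json
facoda fit-coda --cohort kept.csv --outcome ldl
```

prints (seed 0):

```
Compositional OLS: ln ldl  (n = 5100)
  parts: SFA, MUFA, omega6, omega3
  confounders: age, sex, energy_kcal, carb_pcte, sodium_mg_per_1000kcal, physical_activity, sleep_h, screen_time, single_parent, siblings, zbmi
  unadjusted R^2 = 0.0049, F p = 1.666e-05

  first-pivot coefficients (part vs geometric mean of the rest):
         SFA: beta = -0.0182  SE = 0.0242  p = 0.4532
        MUFA: beta = +0.1556  SE = 0.0507  p = 0.002175
      omega6: beta = -0.1136  SE = 0.0314  p = 0.0002941
      omega3: beta = -0.0238  SE = 0.0180  p = 0.1864
```

The omega-6 row says: a one-unit increase of the first pivot coordinate
(more omega-6 relative to the geometric mean of the other fatty acids)
lowers log LDL-C by 0.114 (p ≈ 3e-4) — the generator planted −0.110, and the
refit recovers it within sampling error.  The composition alone explains
0.49 % of LDL-C variance (unadjusted R²), typical of single dietary
exposures.

The change matrix from the published coefficient rows:

```
facoda change-matrix --outcome ldl
ldl (ratio, delta = 4.0 points; rows: to, columns: from)
           SFA    MUFA  omega6  omega3
SFA     1.0000  0.9944  1.0229  0.9958
MUFA    1.0047  1.0000  1.0279  1.0007
omega6  0.9811  0.9758  1.0000  0.9771
omega3  0.9992  0.9938  1.0223  1.0000
```

Moving 4 percentage points of the fatty-acid composition from SFA into
omega-6 PUFA (row `omega6`, column `SFA`) multiplies expected LDL-C by
0.981 — a ~1.9 % predicted decrease.  Entries that drain the small omega-3
part (mean 4.2 %) down to 0.2 % are flagged as extreme extrapolation.

The same objects are available as a library
(`facoda.CompositionalOLS(...).fit()`, `facoda.fit_substitution`,
`facoda.change_matrix`, `facoda.generate`), and `facoda run-all --outdir out`
produces the full report bundle (summary, variation matrix, all model
tables, change matrices, figure data, run manifest).

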
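# Methods

## The standard-human index

Height in adults is a stable body-size parameter; weight is not. The index
`d = h − BSA` (numeric value of height in meters minus numeric value of the
Mosteller BSA in square meters, units discarded) measures relative weight
excess independent of height: substituting `BSA = sqrt(100·h·w/3600)` and
solving `d = 0` gives `w = 36 h` kg, the *standard-human* weight (62.28 kg at
1.73 m). At fixed height, `d` is strictly decreasing in weight and therefore
in BMI. Heights are stored in meters everywhere; the Mosteller formula
converts to centimeters internally, since the formula presumes centimeters.

## Reference regression and limits

Expected THV is linear in `h` and `d`:

    THV_expected = coef_height·h + coef_d·d + intercept

The pinned published model is (456, −221, −335) mL with a fixed ±142 mL
band. The band is interpreted as a 95% *prediction* half-width, constant
across subjects (not leverage-adjusted): the published upper-limit equation
is literally `intercept + 142 = −193`, which forces this reading. On refit,
`half_width = z_{(1+coverage)/2} · residual_sd` with
`residual_sd = sqrt(RSS/(n−3))`; whether the original ±142 was a z-multiple
or an empirical residual quantile is unknowable from the printed values, so
the refit path exposes the z-based rule only. Under the z-rule the implied
residual SD is 142/1.96 ≈ 72.4 mL, which seeds the generator default.

The fit itself is ordinary least squares (statsmodels). Degenerate designs
(constant height, constant `d`, collinear regressors, n < 10) raise a
`FitError` naming the offending regressor. `coef_d` is stored signed (−221),
so prediction is a plain dot product.

Classification: a subject is *abnormal* iff `THV_measured − THV_UL > 0`; the
boundary (difference exactly zero) counts as within the expected range.
Subjects without a measured THV receive the anthropometric half of the
assessment with the abnormality flag undetermined, and are excluded from
prevalence denominators (reported separately).

Indexation: `THV/h` (mL/m) and `THV/BSA` (mL/m²) differ by the correction
`THV/h − THV/BSA`, zero exactly at `d = 0` and signed like `BSA − h`.
Published BSA-indexed means convert to the height scale as
`value · mean_BSA / mean_height`, i.e. evaluated at the cohort's mean body
build.

## Risk stratification

High cardiovascular risk is triggered by any of: CACS ≥ 10 Agatston units
(inclusive threshold), systemic arterial hypertension, treated type 2
diabetes, or smoking and dyslipidemia simultaneously. One of smoking or
dyslipidemia alone leaves a subject low-risk. The reference stratum for
fitting is low risk *and* normal BMI (17.8 ≤ BMI < 25). BMI below 17.8 is an
explicit `below_range` class rather than an error, so underweight subjects
flow through assessment but never enter the reference stratum.

## Statistics

- Two-group comparison: classic Student (pooled-variance) t-test by default,
  Welch via `equal_var=False`. The pooled default matches the method's
  naming convention for these comparisons; Welch is exposed as the safer
  option for unequal spreads.
- Contingency tables: Pearson chi-square without continuity correction.
- Agreement: mean difference (mL and % of the pairwise mean), Bland–Altman
  95% limits of agreement (mean ± 1.96 SD of differences), Pearson r, and
  the ICC as two-way random effects, absolute agreement, single measure —
  the standard choice for method-agreement questions; the variant is carried
  in the output metadata. Constant pairs leave the ICC flagged undefined.
- P-values are reported raw; no multiple-testing correction is applied, and
  outputs say so implicitly by reporting nothing else.

## Synthetic cohort generator

The generator emulates the *structure* of a contemporary CAC-screening
cohort so that every pipeline stage and the refit path are testable without
patient data. Defaults: 65.2% female; BMI-class mixture 25/40/35%
(normal/overweight/obese, no below-range mass); per-(sex, class) BMI
truncated normals with means/SDs from the cohort's stratum table (e.g.
F-normal 22.87 ± 1.72, M-obese 33.44 ± 3.26), truncated to the class bounds
(obese capped at 60 kg/m²); heights per sex ~ N(1.62, 0.06) m (F) and
N(1.75, 0.07) m (M), truncated to [1.40, 2.10] — back-solved from the
published per-cell BSA and BMI via `h = (36·BSA²/BMI)^(1/3)`; weight derived
as `BMI·h²`, which makes BMI-class targeting exact and mirrors how the
strata are defined.

Risk class is drawn per (sex, BMI class) with the published cell high-risk
fractions (from 133/418 for F-normal to 244/293 for M-obese). Risk-factor
booleans are drawn conditionally on the class and then constrained so the
risk rule holds by construction: low-risk subjects get no hypertension or
diabetes, never smoking and dyslipidemia jointly, and CACS < 10 (70% exact
zero, else uniform 1–9); high-risk subjects draw CACS ≥ 10 with probability
0.7 (10 + rounded log-normal) and, if no trigger fired at all, the CACS
trigger is forced — only the 10 AU threshold matters downstream. The overall
published risk-factor marginals (hypertension 75%, diabetes 20%) are *not*
jointly achievable with the risk rule and the ~56% high-risk fraction (75%
hypertensive leaves only 25% normotensive, fewer than the low-risk share),
so the high-risk conditional probabilities (SAH 0.85, T2DM 0.36) were chosen
once to land the overall marginals as close as the rule permits; smoking
(21%) and dyslipidemia (53%) are applied in both classes.

Measured THV is generated additively around the reference plane:

    THV = 456·h − 221·d − 335 + Δ(sex, class, risk) + N(0, σ),  floored at 150 mL

with σ = 72.4 mL and Δ the published measured-minus-expected cell means
(−32.9 … +98.2 mL; positive in every high-risk cell). Whether disease
enlargement is additive or multiplicative in body size is not established;
additive is the minimal model and is what the cell means identify. Age is
drawn per cell for realism but feeds no computation. All draws flow through
one `numpy` Generator seeded from the config; identical configs give
identical cohorts.

What the generator does *not* emulate: correlation between risk factors
beyond class-conditional marginals, measurement error structure, secular
trends, chamber-level volumes, or any non-Gaussian residual shape. Passing
tests on generated cohorts therefore demonstrate correctness of the
machinery and calibration *under the stated model*, not transportability to
real populations.

## Numerical and reporting choices

- All derived quantities are computed at full float precision; rounding
  (BSA 2 dp, BMI 1 dp, volumes to integer mL) happens only at display time.
  The published worked-example table chained intermediate rounding (its two
  lightest rows print expected THV 1 mL below direct evaluation, and its
  heaviest row prints BMI 29.8 where direct evaluation gives 29.74); the
  implementation does not replicate that chaining.
- Model JSON serialization uses Python's shortest-round-trip float repr, so
  save → load is bit-exact.
- Validation errors name the offending field; cohort CSV reading reports
  per-row issues (row, column, reason) and a strict mode turns any issue
  into a failure.
- Problem sizes in the test suite: oracle-equivalence checks use 100
  instances of n ≤ 30; parameter recovery uses one 50,000-subject cohort;
  calibration and structure checks use 10,000–20,000 subjects — large enough
  that 3-SE bands are decisive, small enough to keep the suite fast.

## Known limitations

- The pinned model reflects one mid-diastolic, non-contrast-CT,
  single-center cohort; applying it elsewhere requires refitting
  (`thvnorm fit`).
- The constant prediction band ignores leverage; subjects at extreme heights
  or builds have mildly anti-conservative limits.
- Sex-pooled reference equation by design; sex enters only through strata.
- The multivariate predictor modelling and ANOVA-style decompositions that a
  full epidemiological analysis would add are out of scope here.
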
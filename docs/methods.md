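# Methods

## Model and estimands

All analyses are observed-variable path models estimated by ordinary least
squares. For exposure X, mediator M, outcome Y and covariates Z:

* **Simple mediation.** `M ~ X + Z` gives the first-stage path *a*;
  `Y ~ X + M + Z` gives the second-stage path *b* and the direct effect
  *c′*; `Y ~ X + Z` gives the total effect *c*. The indirect effect is
  *a·b* and, because the three equations share one covariate set,
  *c = c′ + a·b* holds as an algebraic identity (to machine precision, and
  on every bootstrap resample — a property the tests assert rather than
  assume). The proportion mediated is 100·a·b/c, reported only when
  |c| ≥ 1e−8; below that floor it is returned as undefined rather than as
  an exploding ratio.

* **Two-stage moderated mediation.** A moderator W may shift either path.
  Each stage is fit hierarchically — covariates, then main effects, then
  the stage's interaction — reporting per-step coefficients, R², ΔR² and
  the increment test F = (ΔR²/q)/((1−R²)/(n−p−1)). Variables are z-scored
  (n−1 denominator) *before* products are formed, and the product itself is
  not re-standardized; this makes "one SD below/at/above the mean" of the
  moderator exactly w = −1, 0, +1 on the model scale. Simple effects are
  the linear combinations first(w) = a + w·a_int, second(w) = b + w·b_int;
  the conditional indirect effect is their product; and the high−low
  difference of a stage equals (w_high − w_low)·interaction exactly, which
  the tests check as an identity. Coefficient tables from standardized
  fits label the column `B` as published tables in this literature do, but
  it should be read as a standardized coefficient.

  Because published simple-effect tables computed this way are sometimes
  internally inconsistent with a single linear interaction model, the
  package makes no attempt to reproduce any specific published cell values
  for these tables; it implements the stated protocol and verifies its
  algebraic identities and its calibration instead. Both the full-sample
  interaction protocol (default) and the subgroup protocol (dichotomize W,
  fit within halves) are available, since the two are known to disagree in
  low-power settings.

## Bootstrap inference

Intervals for all effects come from the nonparametric bootstrap: whole
rows resampled with replacement at the original n, every regression refit
per resample. Defaults follow the common practice for these models:
5000 resamples, 95% level, bias-corrected percentile method.

* **Bias correction.** z₀ = Φ⁻¹(fraction of bootstrap draws strictly below
  the point estimate, with draws exactly equal counting half — the
  half-tie rule keeps z₀ finite under heavy ties). Bounds sit at the
  Φ(2z₀ + z_{α/2}) and Φ(2z₀ + z_{1−α/2}) empirical quantiles; with z₀ = 0
  they reduce exactly to the percentile bounds. The proportion is clamped
  to [1/(2B), 1−1/(2B)] so z₀ stays finite even in degenerate batches.
  Acceleration (BCa) is deliberately not implemented; the method targeted
  here is the plain bias-corrected percentile bootstrap.
* **Quantile convention.** Inclusive order statistics with linear
  interpolation (numpy default). This matters: bounds read at two decimals
  can move by one unit in the last digit under other conventions.
* **Z column.** Point estimate divided by the bootstrap SE (n−1); a
  delta-method (Sobel) SE for the indirect effect is available by flag.
* **Degenerate resamples.** A rank-deficient resample is redrawn from the
  same generator stream and counted (`redraws`); with continuous data this
  is essentially never triggered.
* **Implementation.** The resample index stream is one
  `rng.integers(0, n, (B, n))` call from `numpy.random.default_rng(seed)`
  made before any other draw, so the whole chain is reproducible and an
  independent re-implementation over the same stream must agree exactly
  (a test does exactly this). Per-resample fits solve batched normal
  equations in einsum/`linalg.solve` rather than constructing model
  objects; a test pins the batched solver to statsmodels OLS output at
  1e−10. For the moderated tables, standardization happens once on the
  full sample and the standardized rows are resampled; re-standardizing
  within each resample is a defensible alternative but changes nothing at
  these sample sizes and would decouple the moderator levels from the
  reported ±1 SD scale.

## Synthetic data

The generator exists to reproduce the statistical structure of a large
cross-sectional survey (n = 6057; six scale totals: childhood trauma,
self-esteem, cognitive reappraisal, expressive suppression, depression and
anxiety symptoms) from its published summary statistics.

* **Scale level.** Multivariate normal with the target mean/SD/correlation
  structure. `exact_moments=True` additionally rotates the draw so the
  *sample* moments equal the targets exactly (the `mvrnorm(empirical=TRUE)`
  construction). This is the right fixture for replication work: the
  original study's estimates are functions of its sample moments, and
  those sample moments are precisely the published numbers, so exact-moment
  data reproduces published point estimates up to input rounding, while a
  plain draw adds dataset-level sampling noise (SD ≈ 0.003 on the indirect
  effect) on top.
* **Demographics.** Only age quantiles (median 34, IQR 30–40) and two
  age–outcome correlations (−0.13 with depression, −0.10 with anxiety) are
  published. Age is a monotone piecewise-linear quantile transform of a
  latent normal pinned at those quantiles, truncated at 18 (upper knot
  70); the transform preserves rank correlations, so the Pearson targets
  survive to within a few hundredths. All other age/sex correlations are
  set to zero — the published sensitivity analysis shows covariates do not
  move the conclusions, and the package's own tests confirm the adjusted
  and unadjusted indirect effects differ by < 0.01 under this structure.
  Sex (1 = female, 0 = male) is filled by quota by default —
  round(n·0.3999), reproducing the published 2422/3635 split exactly at
  n = 6057 — or Bernoulli in sampling mode.
* **PD repair.** Printed correlation matrices are rounded to two decimals
  and, once augmented, need not be positive definite. Repair clips
  eigenvalues at a floor (default 1e−6), reconstructs, renormalizes to
  unit diagonal and iterates; it is a no-op on already-PD input (the
  published 6-variable matrix plus the age column is PD as printed, so
  the default spec needs no repair), idempotent, and reports its maximum
  elementwise perturbation.
* **Item level.** Compound-symmetric latent items
  (x_j = √ρ·common + √(1−ρ)·unique) so the continuous battery's Cronbach's
  α equals kρ/(1+(k−1)ρ) in population — e.g. k = 28, ρ = 0.222 gives
  α = 0.889, the trauma questionnaire's published reliability.
  Discretization to Likert categories (equal-probability normal thresholds
  by default) attenuates α by a few hundredths; a `rho_inflation` knob can
  compensate and is off by default.
* **Structural.** m = a·x + a_w·xw + g_m·w + ε, y = c′·x + b·m + b_w·mw +
  g_y·w + ε, with known coefficients attached to the output for recovery
  tests. With zero interactions its implied covariance is available in
  closed form and matches the moment generator's (tested at n = 200 000).

What the generator does **not** emulate: the bounded, discrete, skewed
marginals of real questionnaire totals (the published distribution checks
note the emotion-regulation scores are non-normal; the default here is
Gaussian, and scale totals can stray outside their nominal ranges),
response styles, and missingness. Passing tests therefore demonstrate
correctness of the estimators and their calibration under the published
moment structure — not robustness to real-data pathologies.

## Scale scoring

Declarative `ScaleDefinition`s (JSON-serializable) with reverse keying as
min + max − response before aggregation. Built-ins follow the canonical
instrument layouts: the 28-item trauma questionnaire scores five 5-item
subscales (5–25 each) and ignores its three minimization/denial items; the
emotion-regulation questionnaire splits 6 reappraisal / 4 suppression
items on a 1–7 scale; self-esteem is 10 items, 1–4, five reverse-keyed,
total 10–40. The symptom scales default to the standard 0–3 coding summed
(0–27 / 0–21) — the coding consistent with the published descriptives
(depression mean 4.19, SD 4.90) — with a 1–4/mean variant available,
since instrument anchors are sometimes printed 1–4 while totals are
reported on the 0-based scale. Cronbach's α uses the variance formula with
n−1 denominators and refuses degenerate input (< 2 items, < 3 respondents,
zero total variance) explicitly.

## Numerical choices and problem sizes

* SDs, variances and standardization use n−1 throughout, matching sample
  descriptives.
* p-values are two-sided; stars at 0.05/0.01/0.001.
* Rank deficiency is detected by pivoted QR and reported with the
  offending column names.
* Perfectly collinear pairs report r = ±1 with p = 0.
* Calibration studies in the test suite run at the sizes the estimands
  need: parameter recovery at n = 50 000 (3 Monte-Carlo-SE tolerance),
  interval coverage over 500 replicates of n = 500 with 1000 resamples
  each (93–97% acceptance band for the nominal 95%), and the type-I error
  of the high−low indirect-difference test under no moderation at the same
  size (5% ± 3 binomial SEs). The null configuration keeps a and b nonzero
  — that is the relevant "no moderation" null; with a = b = 0 the product
  statistic is non-regular and the test would be conservative.

## Known limitations

* Single mediator, single moderator per stage (shared by default, distinct
  allowed); no serial/parallel multiple mediators, no latent-variable SEM,
  no Johnson–Neyman regions.
* OLS with homoskedastic classical standard errors for the point fits;
  inference on the products comes from the bootstrap, not from those SEs.
* The bootstrap treats rows as exchangeable; no clustering or weights.
* Gaussian synthetic marginals as discussed above; a skewed-marginal hook
  (monotone transforms, as used for age) is the natural extension and the
  age transform shows the pattern to follow.
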
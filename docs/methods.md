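# Methods

## Scope and model

`pfhaqlink` links total scores on the SF-36 physical functioning scale
(PF-10) and the HAQ disability index (HAQ-DI) through a common latent
disability metric.  All calibrations use adjacent-category logit models
for ordered polytomous responses,

P(X_j = k | θ) ∝ exp( Σ_{h≤k} a_j (θ_d(j) − b_jh) ),  k = 0 … m_j − 1,

with the convention that higher θ means worse physical function.  The
PF-10 enters as 10 reverse-coded items with 3 categories (0–2); the
HAQ-DI enters as its 8 category scores, each an ordered 0–3 "item".
Three nested specifications are implemented:

- **PCM** — all a_j fixed at 1 (the Rasch case; the summed score is then
  a sufficient statistic for θ, which makes total-score linking exact);
- **GPCM** — a_j free, one dimension;
- **MIRT2** — between-item two-dimensional GPCM: PF-10 items load on
  dimension 1, HAQ categories on dimension 2, each latent margin
  standard normal, correlation ρ estimated.

Assumptions: conditional independence of items given θ; a normal latent
prior (used both for identification and for EAP scoring); and, for the
unidimensional models, that both instruments measure one common trait.
The MIRT2 model is the within-package check on that last assumption.

## Estimation

Marginal maximum likelihood via EM.  The latent prior is discretized on
a fixed rectangular grid of 61 equally spaced nodes on [−6, 6] per
dimension with normal-density weights renormalized to sum to one (2-D:
product grid with bivariate-normal weights).  A rectangular grid was
chosen over Gauss–Hermite for simplicity and reproducibility; for items
with ≤ 4 categories and n in the thousands the discretization error is
far below sampling error (the EAP check against 10× finer integration
agrees to < 1e−6).

The E-step computes each person's posterior over nodes (for MIRT2 the
likelihood factorizes by dimension, so joint posteriors reduce to two
matrix products).  The M-step maximizes each item's expected
complete-data log-likelihood with L-BFGS using analytic gradients
(thresholds, plus log-discrimination under GPCM/MIRT2); because the
M-step increases the EM minorant, the observed-data log-likelihood is
monotone non-decreasing, which the tests assert to 1e−8.  ρ is updated
by a profile-likelihood grid scan (step 0.05 within EM iterations;
after convergence a 0.01-step scan refined once on a 0.001 grid).
Convergence: maximum absolute parameter change < 1e−4, cap 500
iterations; non-convergence raises with the likelihood trace attached.
Categories never observed in the data are collapsed into their lower
neighbour with a warning (strict mode errors instead).  A minimum
sample size of 100 is enforced; recovery quality is only vouched for at
the cohort sizes the tests use (n ≈ 2000: threshold RMSE < 0.10,
threshold correlation > 0.99, ρ̂ within ±0.05 of the generating value).

## Score tables and linking

Summed-score EAP tables use the Lord–Wingersky convolution recursion for
P(S = s | θ_q), then θ(s) = Σ_q θ_q P(s|θ_q) w_q / Σ_q P(s|θ_q) w_q.
Tables are strictly increasing in the disability-coded summed score (a
violation raises).  Under MIRT2 each instrument's table is computed on
its own dimension against the standard-normal margin of the joint
prior — items load on a single dimension, so integrating the bivariate
prior over the other dimension reduces to the margin — and linking then
compares the two EAP scales directly, interpreting the concurrent
estimation of the two dimension-specific EAPs as placing them on a
common metric.  This was a genuinely open design point; conditional-
expectation linking given the other dimension is the main alternative
and is deliberately not implemented.

Nearest-EAP linking maps each score s of instrument A to
argmin_t |θ_A(s) − θ_B(t)|.  Ties (two equidistant candidates) resolve
to the score indicating better function; scores whose EAP lies beyond
the other instrument's most extreme table entry clip to the extreme
score, never extrapolate.  Crosswalks are total over the 21 attainable
PF-10 and 25 attainable HAQ-DI values, monotone, and deterministic
given responses, model and scoring method.

The published RA crosswalk ships as packaged data
(`pfhaqlink/data/published_crosswalk.csv`, SDI and ADI blocks, raw and
norm-based PF-10 columns) and is never recomputed at install time.

## Instrument scoring details

- HAQ item-to-category partition: the standard 2/2/3/2/3/2/3/3 layout
  (dressing and grooming, rising, eating, walking, hygiene, reach,
  grip, activities), configurable because published sources rarely
  print it.
- SDI rule: a category's score is raised to 2 when its aids/devices-or-
  help flag is set and the item maximum is below 2; ADI ignores flags.
  The rule lives in one function so variants can be swapped in.
- Missing data: complete-case by default.  An optional HAQ rule is
  provided but off by default: with ``min_categories=6`` the total is
  the mean over present categories when at least 6 of 8 are scored
  (such totals need not be multiples of 0.125).  Imputation is out of
  scope.
- Norm-based PF-10 scoring: T = 50 + 10 (raw − μ)/σ with defaults
  μ = 83.2625, σ = 23.75, recovered from the 21 published (raw, T)
  pairs by a minimax fit (the printed T-scores are rounded to one
  decimal, so the feasible (μ, σ) region is defined by rounding radii;
  least squares lands just outside it, the Chebyshev fit inside).
  `scripts/fit_norm_coefficients.py` regenerates them.

## Item fit

For each item, persons are split into low/average/high groups by
tertiles of the EAP computed from the *remaining* items (rest
posterior).  Using the item's own response to locate its groups makes
the statistic sharply anti-conservative, which is why the rest
posterior is used; tertile cutpoints use empirical-CDF quantiles so
tied persons share a group and duplicating the sample leaves the
grouping (and therefore the ES) unchanged.  Within each group the
observed mean item score is compared with the mean of the model-implied
expected score over each member's rest posterior:

ES = |observed − expected| / m_j,

acceptable when every ES < 0.10 (score-frequency differences of 2.5%
for 4-category, 3.33% for 3-category items).  An accompanying
Lagrange-multiplier-type statistic is reported: the quadratic form of
grouped score residuals with a plug-in variance (posterior-integrated
item-score variance), referred to χ² with df = number of groups.  This
is an approximation — it ignores parameter-estimation uncertainty and
residual covariance — so its null p-values are somewhat conservative;
the ES cutoff is the primary gate.

## Validation battery

- **ICC(A,1)**: two-way, absolute agreement, single measurement, from
  the mean-squares formulas, with the F-based 95% CI; point estimate and
  CI cross-checked against pingouin in the tests.  ≥ 0.70 is flagged as
  adequate for group-level comparison.
- **Bland–Altman**: differences follow the observed-minus-predicted
  convention; LOA = mean ± 1.96 SD of differences; a four-panel plot
  helper renders the standard figure.
- **Responder rule**: DAS28 good response ⇔ improvement ≥ 1.2 and final
  ≤ 3.2; missing values are unclassifiable and excluded upstream.
- **Cohen's d** for change: mean change / SD(baseline) by default
  (change-score SD available via an argument), signed so improvement is
  positive on both disability- and function-coded scales.  Baseline SD
  was chosen as the default because it is the common responsiveness
  convention for patient-reported outcomes; the choice is configurable
  precisely because conventions differ.
- **Relative validity**: RV = F_predicted / F_observed from one-way
  ANOVAs of change on responder status; 95% BCa bootstrap CI (B = 2000
  default) resampling persons with a seeded generator, jackknife
  acceleration, and redraws of degenerate resamples (a group emptied by
  resampling).  With zero bias and acceleration the interval reduces to
  the percentile interval (asserted in tests); the implementation is
  cross-checked against scipy's BCa.

## Synthetic data

The generator emulates the structure the analysis needs, not any real
cohort: θ standard normal (optionally bivariate with ρ = 0.73 by
default); stylized threshold layouts with PF-10 item locations spanning
better-function levels (−1.6 … 0.8) and HAQ category locations shifted
toward worse function (−0.8 … 1.6), so the two test-information curves
peak at different disability levels; aid/device flags from a logistic
model in θ (intercept −2, slope 1), concentrating SDI–ADI differences
at worse function; and a longitudinal block in which ~49% of persons
are good responders improving 0.9 latent SD (others 0.1) with 0.3 SD
follow-up noise, and DAS28 pairs constructed to satisfy or fail the
responder rule by design.  Scenario defaults mirror the cohorts the
methodology targets: n = 1791 calibration-like, n = 532 baseline /
n = 276 longitudinal cross-validation-like with latent mean shifted
−0.5 (a healthier early-RA cohort).  Under these defaults the pipeline
lands in the empirically typical ranges (observed-vs-predicted ICCs
0.7–0.9; 6-month effect sizes 0.3–0.6), which the tests assert as
bands, not point claims.

What the generator does **not** emulate: real item-level response
styles, DIF across demographics, registry covariates, missingness
mechanisms, or floor/ceiling pile-ups beyond what the threshold
layouts induce.  Passing tests therefore demonstrate the correctness
and internal consistency of the machinery under the assumed model, not
the empirical adequacy of any particular crosswalk for a new
population.  Note also that SDI-scored category scores deliberately
violate the generating IRT model (the aids/devices bump is a scoring
rule, not a response process), so parameter-recovery checks use
unadjusted category scores.

## Problem sizes in the tests

Recovery and fit-diagnostic suites use n = 2000 and n = 1791 with 20
seeded replicates and judge medians (or pass rates), matching the
cohort scale at which the methodology is meant to operate while keeping
the full suite in the minutes range.  Oracle-equivalence checks run on
3-item toy instruments where exhaustive enumeration is feasible.

## Known limitations

- Crosswalks are group-level devices; individual-level conversion is
  out of scope by design (wide limits of agreement are expected).
- The LM-type statistic is an approximation (see above).
- No graded-response or nominal models, no MCMC, no DIF analysis.
- DAS28 is consumed as given; computing it from joint counts/ESR is out
  of scope.
- Exact numerical agreement with calibrations produced by other IRT
  software is not claimable: quadrature, M-step internals and stopping
  rules differ between implementations.
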
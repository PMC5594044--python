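# Methods

## Model

`ethomix` fits a multilevel baseline-category (multinomial) logit to
long-format scan records. The unit of analysis is the instantaneous scan:
one behavioral category per individual per predetermined instant. Continuous
focal-follow data (durations, transition times) are out of scope.

With categories 1..K and reference category r (by default the last in the
ethogram), the model has K − 1 contrast equations

    log(π_k / π_r) = x'β_k + Σ_f v_f[g_f, k]        for k ≠ r,

one per non-reference category, with the reference logit fixed at exactly 0
for identifiability. Each random-effect factor f (individual, household,
month, …) contributes a group-level deviation vector v_g across the K − 1
equations,

    v_g ~ MVN(0, Ω_f),   Ω_f = diag(σ_f) R_f diag(σ_f),

and the outcome is a single categorical draw from the softmax of the
augmented logits. The cross-category correlations R_f are the quantity of
substantive interest: a negative entry means groups that do relatively more
of one behavior do relatively less of another, both measured against the
reference. Household and month factors receive full covariance matrices just
like the individual factor; a diagonal-only option
(`REFactorSpec(full_covariance=False)`) exists for factors with few groups,
where correlations are weakly identified. Varying slopes and
temporally-structured (Gaussian-process) effects are not implemented.

Assumptions worth stating plainly: scans are conditionally independent given
the covariates and the random effects (no residual within-day
autocorrelation); random effects are exchangeable within factor (month
effects carry no notion of adjacency); covariate effects are common across
groups (varying intercepts only).

## Priors and parameterization

All priors center at zero so that non-zero posteriors reflect evidence:

| parameter | prior | default | knob |
|---|---|---|---|
| intercepts | Normal(0, s) | s = 5 | `PriorConfig.intercept_scale` |
| slopes | Normal(0, s) | s = 1 | `PriorConfig.slope_scale` |
| RE scales σ | half-Cauchy(0, c) | c = 2 | `PriorConfig.sigma_scale` |
| correlation Cholesky | LKJ(η) | η = 2 | `PriorConfig.lkj_eta` |

The scales are wide relative to coefficients seen in scan-sampling studies
(|β| rarely beyond ~3.5 on standardized covariates). Sampling runs on the
unconstrained scale: log σ with its Jacobian, and the correlation Cholesky
factor mapped from tanh-transformed free coordinates row by row (unit-norm
rows), with the transform's log-Jacobian and the LKJ density (including its
normalizing constant) added explicitly. Random effects use the non-centered
parameterization v = diag(σ) L z with z ~ N(0, I), which removes the
scale/location funnel from the posterior geometry.

## Estimation

The sampler is a No-U-Turn HMC variant written against analytic gradients of
the joint log density (verified against finite differences in the test
suite): recursive trajectory doubling with slice acceptance, divergence
declared at an energy error of 1000, dual-averaging step-size adaptation
toward a target acceptance statistic (default 0.9; correlated
high-dimensional posteriors reward conservative step sizes), and a diagonal
mass matrix re-estimated in doubling warmup windows, Stan-style
(15% step-size settling, variance windows from 25 iterations doubling, 10%
final buffer). Defaults are 3 chains × 2000 iterations with the first half
as warmup; warmup draws are discarded and never thinned into the posterior.
Runs are deterministic given the seed. Poor mixing does not raise: the fit
returns with R-hat > 1.01, bulk ESS < 100, or divergences flagged by
`diagnostics()` (computed via arviz), and the verdict string says what is
flagged.

`fit_map` (L-BFGS on the same log density) exists for fast invariance
checks — e.g. that relabeling the reference category changes β but not the
fitted probabilities — not as an estimation method.

## Model comparison and summaries

WAIC is computed from the pointwise log-likelihood matrix recorded with
every fit: lppd_i by log-sum-exp over draws, p_i as the sample variance
(ddof 1) of the pointwise log-likelihood, reported on the deviance scale
waic = −2 Σ(lppd_i − p_i) with SE = √(n·Var_i). The comparison table reports
Δ against the best model with a *paired* SE — √(n·Var_i) of the pointwise
difference — because the two models' pointwise scores are correlated;
weights are exp(−Δ/2) normalized. With a single observation the SE is 0 by
convention.

Credible intervals are equal-tailed percentile intervals throughout: 0.96
for coefficient and RE summaries (with an `excludes_zero` flag), 0.89 for
predictions. Correlation summaries transform every posterior draw through
L L' and summarize the draws of ρ — never the correlation of posterior
means.

## Predictions and contrasts

`link_mn` evaluates, per posterior draw and covariate scenario, the design
row (standardized with the training record; squared terms are squares of the
standardized value, matching the design builder) times that draw's β, then
the softmax. Random effects enter per scenario mode: `fixed_only` (zero,
the default — the "average group" prediction), `unit` (a named group's
stored deviations; when both individual and household IDs are given, both
effects are added), or `marginal_new_unit` (a fresh MVN draw from that
posterior draw's covariance — an unseen group).

Scenario differences are summarized on the distribution of per-draw
differences (mean, percentile interval, Pr(diff > 0)). Overlap of two
marginal prediction intervals is deliberately not offered as a test: those
intervals carry uncertainty from all parameters, not from the contrast.
The package reproduces the classic pitfall this machinery exists for: a
covariate can leave the k-vs-reference coefficient at zero yet clearly move
the probability of k, because the reference category itself responds to the
covariate. The acceptance suite demonstrates this with a generating model
whose day coefficient is exactly zero for one category.

A caution the fixed-only mode inherits from the nonlinear link: softmax of
the population-mean coefficients is the probability for an *average group*,
not the population-average probability. With modest random-effect scales
(σ ≲ 0.3) the two agree closely — the intercept-only consistency check runs
at σ = 0.2, where fixed-only predictions reproduce raw sample proportions to
well under 0.01 — but with strong heterogeneity (σ ≈ 1) and few groups they
can differ by several probability points. Use `marginal_new_unit` when the
population-average quantity is the target.

## Synthetic generator

`ethomix.simulate` emulates household-based scan sampling: individuals are
assigned round-robin to households (every household non-empty); on each
sampling day a subset of households is drawn without replacement (no
household observed more than once per day) and every resident of a visited
household is recorded at each 30-minute scan between the day's start and end
times. Sampling days cycle through the week with a random phase, so a 7-day
monthly period covers each weekday once. Covariates: age per individual
(Normal(31, 15) truncated at 15 years), household wealth (Normal(8.6, 0.9),
a log-currency index) and size (Poisson(7)+1 residents), monthly rainfall
(Gamma with mean 222 mm, SD ≈ 112), day-of-week dummies for Saturday/Sunday
against a weekday baseline, and time of day as a fraction of 24 h. All
continuous covariates are z-scored (sample SD, n−1) before entering the
design, and the mean/SD record is reused for prediction grids.

Two presets: the desk scale (20 individuals, 10 households, 6 periods,
5 households/day, 7 scans/day ⇒ ~2,940 records) sized for test suites, and a
field scale (45 individuals, 25 households, 12 months, dawn-to-dusk scans,
K = 14) matching a realistic year-long campaign. A rare-category truth
preset (one category with π < 0.005) exercises the regime where the
posterior for a category is prior-dominated — the practical argument for
user-directed merging of rare categories (`collapse_categories`; no
automatic rarity threshold is applied).

What the generator does **not** emulate, and what passing tests therefore do
not establish: within-day temporal autocorrelation of behavior, observer
error or missed scans, seasonal confounding between rainfall and the month
effects, unbalanced household sizes, and informative sampling (which
households get visited is independent of behavior). Recovery results say the
implementation is correct under its own assumptions, not that those
assumptions hold in field data.

## Numerical choices

- Log-probabilities are computed in log space with max-subtracted
  log-sum-exp; no probability clipping anywhere.
- The z-score denominator is the sample SD (n−1); zero-variance covariates
  are an error, not a silent drop.
- Polynomial design columns square the standardized value (z, z²), and
  prediction grids recompute squares from the standardized value, so the two
  paths agree exactly.
- Category codes are 0-based in ethogram order internally; the reference
  defaults to the last listed category and is overridable.
- Cluster IDs are densely re-indexed (sorted order) with original labels
  retained for reporting.
- Rows with missing covariate or factor values are dropped with a logged
  count (no imputation).
- Duplicate design columns raise immediately (rank deficiency by
  construction), as does a categorical term whose baseline level never
  occurs.
- Degenerate posteriors (point masses) are tolerated in summaries: SDs are
  reported as 0 and coverage checks use a 1e-9 relative tolerance.

## Problem sizes used in the checks

The recovery calibration fits 20 replicate desk-scale campaigns (K = 5,
20 individuals, ~2,940 scans, 5 design columns, full individual covariance
with strong ±0.6–0.7 correlation entries) with single 500-iteration chains
at target acceptance 0.85 — enough for stable 89% intervals on this
posterior — and pools coverage over all β entries. The WAIC and consistency
checks use one campaign each. These sizes are the package's desk-scale
defaults; the 3×2000 sampler default remains appropriate for real analyses.

## Known limitations

- No varying slopes; no Gaussian-process/temporal kernels; no DIC or
  cross-validation criteria (WAIC only).
- The NUTS implementation is single-threaded pure NumPy; fits with K ≳ 10,
  several crossed factors, and tens of thousands of scans are feasible but
  slow (hours, as expected for this model class).
- Maximum-likelihood and variational fits are not provided; `fit_map` is a
  diagnostic device.
- WAIC's p_waic uses the sample-variance (ddof 1) convention; reference
  implementations using the population variance will differ by O(p/S).
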
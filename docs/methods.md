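# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `airmort`.

## The modelling problem

The response is the daily cardiorespiratory mortality rate among people
over 60 in a large subtropical city, expressed as deaths per 10⁵ elderly
inhabitants of the corresponding calendar year. The six covariates are the
citywide daily mean concentrations of PM₁₀, NO₂ and SO₂ (µg/m³) and daily
mean temperature (°C), relative humidity (%) and wind speed (m/s), all at
lag 0. Seasons follow the subtropical convention: rainy = October–March
(summer: temperature and humidity peaks), dry = April–September (pollution
and mortality peaks). Three model variants are fitted throughout: pooled
(all days), rainy-only, and dry-only.

## Preprocessing rules

* **Daily station mean:** a station-day is kept only when strictly more
  than 75% of its 24 hourly values are present (> 18 hours). The "more
  than" is read literally — exactly 18 of 24 does not qualify. The
  threshold is a parameter (`min_present`).
* **Citywide mean:** the unweighted mean over the eligible stations
  reporting that day. Days missing at some but not all stations use the
  present subset; this maximizes usable days and keeps the completeness
  rule per station, where it operates. Days with no reporting station stay
  missing.
* **Modeling rows:** complete-case (listwise) deletion; no imputation.
* **Rate:** deaths / elderly population × 10⁵, with the population constant
  within each calendar year (step interpolation).
* **Scaling:** the MLP consumes covariates and response min–max scaled to
  [−1, 1]; parameters are computed on the full complete-case table before
  season filtering and before the train/validation/test split, and stored
  with the dataset so predictions return to the original scale. The same
  covariate scale is thereby shared by the pooled and season models, which
  keeps connection-weight importances comparable across them. The GLM uses
  unscaled covariates, so its coefficients are per-unit natural-scale
  effects.

## The MLP

Feed-forward, one or two hidden layers, single output. Hidden sizes come
from the grid {5, 10, 15, 20, 25, 30, 35}; two-layer variants use equal
sizes in both layers. Activations: tansig (tanh), logsig, purelin, in all
hidden/output combinations. Weights initialize uniformly in [−0.5, 0.5]
scaled by 1/√fan-in, from a seeded generator.

Training minimizes training-set MSE while monitoring validation MSE every
epoch. The run stops after 6 consecutive epochs without a validation
improvement (`patience`) or at `max_epochs` (default 1000; the reduced
experiment grids use 150), and the parameters from the best-validation
epoch are returned — including, in the worst case, the initial ones.

Optimizers (all operate on the packed parameter vector; the per-sample
output Jacobian comes from a vectorized reverse pass):

* **Levenberg–Marquardt:** damped Gauss–Newton, `(JᵀJ + µI)δ = −Jᵀr`;
  µ ×10 on rejection, ×0.1 on acceptance, start 1e−3, abort above 1e10.
  Only improving steps are accepted, so the training MSE is monotone.
* **Scaled conjugate gradient:** Møller's algorithm (directional
  second-derivative estimate, no line search), restart every p iterations.
* **Powell–Beale CG:** Polak–Ribière β with restart to steepest descent
  when successive gradients lose orthogonality
  (|g_k·g_{k−1}| ≥ 0.2‖g_k‖²) or the direction stops descending; strong
  Wolfe line search with an Armijo backtracking fallback.
* **Bayesian regularization:** LM on β·SSE + α·SSW with MacKay evidence
  updates (γ = p − 2α·tr(H⁻¹), α = γ/2SSW, β = (n−γ)/2SSE). Note that the
  evidence fixed point deliberately trades exact interpolation for smaller
  weights: on noiseless data the final training MSE plateaus above zero
  where the unregularized optimizers reach machine precision. This is the
  intended behavior of the method, not a convergence failure.

Runs that produce a non-finite loss are reported as failed, excluded from
the repeated-run distributions, and counted.

## Search protocol

Per architecture, `repeats` independent runs (default 50; reduced
experiments use 10), each with a fresh random 70/15/15 split (sizes
⌊0.7n⌋/⌊0.15n⌋/remainder) and a fresh initialization, both derived
deterministically from the base seed via `SeedSequence([base, config,
repeat])`. A fresh split per run — rather than one split reused — was
chosen because random train/validation separation is part of the protocol
being repeated. The selection MAPE is computed over **all** observations
(the full real-vs-estimated series); a test-only MAPE is reported
alongside. Ties break to fewer hidden neurons, then lower test MSE, then
lower seed, making selection independent of enumeration order.

The default grid is the fully crossed single-hidden-layer grid
(7 × 4 × 9 = 252 architectures); the two-layer extension is config-driven
rather than folded into the default, because the fully crossed two-layer
product would double the count and the appropriate layer-2 sizing is
underdetermined. Everything about the grid is configurable.

## Variable importance

Connection weights (Olden): `I_ij = w_ij · w_j(out)`, `Imp_i = Σ_j I_ij`,
defined for single-hidden-layer networks only (the statistic has no unique
two-layer generalization, and the best models in practice have one hidden
layer). Percentages normalize |Imp_i| to sum to 100 — the absolute value is
a choice: raw importances are signed, published importance tables are
positive, so the signed values are reported alongside the percentages
rather than discarded. Because importances are computed on weights fitted
to min–max-scaled inputs, the shared scaling scheme is what makes the
percentages comparable across inputs.

The permutation oracle (mean MSE increase over seeded shuffles of one input
column) is an independent ranking check; it shares no code path with the
connection-weight statistic.

## GLM baseline

Gamma family, log link, fitted by IRLS (statsmodels). Basic model: month
(11 dummies), day-of-week (6 dummies), year (numeric trend), temperature,
relative humidity, wind speed. Screening keeps terms with p < 0.05 —
a joint Wald test for dummy groups, the coefficient's Wald p for numeric
terms; the three pollutants are then always entered. Dispersion is the
Pearson χ²/df estimate; CIs are 95% Wald intervals on the coefficient
scale. Year-as-trend (vs. factor) was an open choice; the trend variant was
adopted as the more parsimonious control for the slow decline in both
pollution and mortality. IRLS starts at the intercept-only solution, which
also makes degenerate (near-constant) responses well-posed. A strictly
positive response is required; zero-death days raise an error suggesting a
half-minimum offset, which is off by default because the default scenarios
never produce them at city-scale populations.

## Evaluation

MAPE = mean of 100·|obs − pred|/obs, over the full observation set by
default. Family comparisons use the pooled-variance (Student) two-sample
t-test on APE vectors — pooled rather than Welch because df = n_a + n_b − 2
is the convention that makes the reported degrees of freedom reproducible
from the sample sizes. Boxplot summaries use linear-interpolation quartiles
and 1.5·IQR Tukey fences; the summary CSVs are the plotting interface (no
figure rendering is built in).

## Synthetic-data generator

What it emulates: multi-station hourly pollutant records with missing
hours; dry-season pollutant and mortality peaks and rainy-season
temperature/humidity peaks; daily death counts whose expectation follows a
known log-linear exposure-response model; a growing elderly population.

* **Hourly signal:** citywide sinusoid (period one year; pollutant maxima
  mid-July, temperature/humidity maxima mid-January) plus stationary AR(1)
  deviations (coefficient 0.8, marginal SD 10% of the base level), observed
  per station through a fixed lognormal station factor (SD 0.10) and
  hour-level lognormal noise (SD 0.15), truncated at zero. The parametric
  form is the package's own; the real series are described only
  qualitatively. Base levels (PM₁₀ 35, NO₂ 48, SO₂ 5 µg/m³; 19 °C, 78%,
  2.4 m/s) sit inside the reported 2007–2019 annual-mean ranges.
* **Missingness:** MCAR per hour (default 10%); a block-outage mode exists
  because real monitor gaps are bursty.
* **Mortality:** log rate = log(baseline 4.5 per 10⁵) + effect_scale ×
  (weighted standardized covariates) + 0.2·cos(seasonal term peaking
  mid-dry-season). Weights are nonnegative and sum to 1; `effect_scale`
  (default 0.2 log-units per SD of the composite) sets the overall
  magnitude, which the sum-to-1 weights cannot. Standardization uses the
  simulated long-run mean/SD, recorded on the returned ground-truth object
  so recovery tests are exact. Counts are negative binomial with shape 50
  around rate × population / 10⁵ (shape ∞ = Poisson). Shape 50 gives a
  daily count coefficient of variation near 17% at city scale, consistent
  with the error level of the real series; with these defaults the
  empirical daily rates stay within 1–12 per 10⁵ across seeds, bracketing
  the observed 2.03–8.58 band. An optional season-dependent weight set
  (`effect_weights_by_season`) flips the covariate response between
  seasons — the scenario where stratified modelling should win.
* Mortality is driven by the noise-free citywide daily signal, not the
  noisy station observations, so the generator's ground truth is exact at
  the daily scale while the observable inputs still carry station noise,
  gaps and aggregation error.

What it does **not** emulate: spatial station heterogeneity beyond a scalar
factor, atmospheric chemistry or transport, lagged effects, day-of-week
structure in deaths, reporting artifacts, population age structure. Passing
tests therefore show the pipeline recovers structure *of the kind the
generator produces*; they are not evidence about any particular real city.

## Verification studies and problem sizes

The study routines (`airmort.studies`) use desk-scale sizes, chosen as the
smallest at which the effects are clearly identifiable: three simulated
years with two stations per pollutant; a reduced grid of two hidden sizes
(5, 10) × Levenberg–Marquardt × tansig/purelin with 10 repeats and
max_epochs 150; 10 end-to-end seeds for the ranking and stratification
studies; 100 replicates at n = 5000 for GLM recovery. The dominant-covariate
scenario puts weight 0.7 on PM₁₀; the season-dependent scenario puts weight
0.7 on PM₁₀ in the dry season and 0.7 on temperature in the rainy season.

## Known limitations

* Lag-0 exposure only; no distributed-lag structure.
* Connection-weight importance is undefined for two-hidden-layer networks.
* The Bayesian-regularization trainer uses the evidence approximation with
  a single (α, β) pair, not per-layer priors.
* The GLM assumes gamma dispersion; genuinely Poisson-like rates at small
  populations would call for a count model instead.
* Published coefficient tables and importance percentages from any specific
  real study are not reproducible here: they depend on the original data
  and fitted weights, which are not packaged.
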
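# Methods

## Model and assumptions

`strawsim` simulates strawberry fruit production flower by flower. A flower
is an independent unit: there is no plant-level clustering, no shared bee
budget, and no cap on achene number (real flowers have finitely many
stigmata; the model deliberately omits that ceiling, so extreme pollen loads
translate linearly into weight). For a bloom of `bloom_days` days (default 5),
day *n* (1-based flower age) produces:

| stage | law | parameters (default) |
|---|---|---|
| visits X_n | Poisson(λ) | λ = 4.5 /day |
| pollen Y_n | 25 · X_n (deterministic) | grains_per_visit = 25 |
| fertilized Z_n | Binomial(Y_n, P_n) | P_n = c·exp(−a·n^b), c = 0.8, a = 0.01, b = 3.6 |
| achenes Z_sum | Σ_n Z_n | — |
| weight W | slope·Z_sum + intercept + N(0, σ²) | slope 0.05 g, intercept 2.0 g, σ 3.09 g |

Key modelling assumptions, with their rationale:

- **Poisson visits, identical across days.** Visits are rare, short events
  in a long foraging day, and flower age does not alter bee behaviour. λ is
  exogenous: bee density influences it in a real greenhouse, but no
  functional form is imposed — users set λ directly.
- **Fixed grains per visit.** Deposition is treated as a deterministic 25
  grains; the count is configurable to cover other species, but not random.
- **One-stage fertilization probability.** Receiving (stigma receptivity,
  decaying with age) and accepting (self-compatibility) multiply into a
  single per-grain probability; there is no separate stochastic stage for
  the two, and fertilization is exact binomial thinning — no normal or
  Poisson approximation is ever substituted, even where one would be
  accurate.
- **Unbounded Gaussian residual on weight.** The Bias term stands in for
  genotype and environment. It is not truncated, so weights can (with
  probability ≈ Φ(−3.2) ≈ 6×10⁻⁴ under defaults) come out non-positive.
  They are not clamped; cohort summaries expose `n_nonpositive_weights` so
  the artifact is visible rather than hidden.
- **Marketability is strict**: a fruit at exactly the 10 g threshold is not
  marketable ("over 10 g").

## Closed-form moments

With p_n = c·exp(−a·n^b) and Y_n a 25-fold scaled Poisson
(E Y = 25λ, Var Y = 625λ), binomial thinning gives per day

    E Z_n   = 25 λ p_n
    Var Z_n = 25 λ p_n (1 − p_n) + p_n² · 625 λ

Days are independent, so the bloom totals add. Under defaults

    E Z_sum = 90 · Σ_{n=1..5} exp(−0.01 n^3.6) = 246.291
    Var Z_sum = 3998.06
    E W = 0.05 · 246.291 + 2.0 = 14.315
    SD W = sqrt(0.05² · 3998.06 + σ²)

These formulas are `cohort.expected_summaries` and back the
simulation-vs-analytic acceptance tests. An exact distribution oracle,
`fertilization.exact_zsum_pmf`, builds the full pmf of Z_sum at small
parameters by compounding, thinning and convolving; at full defaults it
yields skew(Z_sum) = 0.2828 and skew(W) = 0.1034 exactly, which is what
simulated cohorts scatter around (single-cohort skewness at N = 10,000 has
sampling SD ≈ 0.0245, so individual runs can print values a few hundredths
away).

## Calibration of the residual SD

σ is the one parameter not fixed by the process description. It is
calibrated once against the target cohort-level weight SD of 4.42 g:

    σ = sqrt(4.42² − 0.05² · 3998.06) = 3.09 g

so the SD of simulated weights reproduces 4.42 g *by construction* — tests
asserting that SD are consistency checks of the calibration identity, not
independent evidence. σ is exposed in config for users with their own
residual estimates.

## Statistical methodology

- **Skewness**: adjusted Fisher–Pearson G1 (`scipy.stats.skew(bias=False)`),
  SE = sqrt(6n(n−1)/((n−2)(n+1)(n+3))) — 0.02449 at n = 10,000 — and
  z = G1/SE with the *unrounded* SE. Published z-scores computed by dividing
  by an SE rounded to 0.024 run ~2% high; expect e.g. 13.4 rather than 13.67
  for the same skewness.
- **K-S tests**: one- and two-sample statistics with asymptotic Kolmogorov
  p-values. When a family's parameters are estimated from the tested sample,
  the plain K-S p-value is anticonservative (Lilliefors effect); it is
  reported uncorrected, as is conventional in this literature, and should be
  read descriptively. Against discrete nulls K-S is conservative; the
  chi-square helper `chisquare_counts` (right-tail bin pooling to expected
  ≥ 5) is the preferred discrete check.
- **3-parameter lognormal MLE**: the global MLE is ill-posed (likelihood
  diverges as loc → min sample), and in the small-shape regime the
  (s, loc, scale) likelihood is a near-flat ridge terminating in the normal
  limit, so raw parameters are not stably identified — only implied moments
  are. The fitter profiles the likelihood over loc (closed-form (s, scale)
  MLE from log-moments at fixed loc) on a log-spaced offset grid spanning
  1e−5 to 1e2 of the sample range below the minimum, refines with bounded
  1-D optimization, and accepts a joint `scipy.stats.lognorm.fit` polish
  only when it improves the likelihood with loc < min. Tests therefore
  assert moment recovery (mean within 1%, SD within 5%), not raw-parameter
  equality.
- **Q-Q data**: ordered sample against normal quantiles at plotting
  positions (i − 0.5)/n, rescaled by sample mean/SD. Because the rescaling
  uses the finite-sample SD, even an exactly-affine-in-quantiles input sits
  within O(|ŝ−σ|) of the identity line rather than exactly on it.
- **Histograms**: Freedman–Diaconis binning, with edges returned so plots
  are reproducible.

## Reproducibility and numerics

One `numpy.random.Generator` seeded from the config drives a whole cohort;
draw order is fixed (all days' visits, then fertilization day by day, then
one weight residual per flower), so identical config + seed gives a
byte-identical cohort CSV (weights serialized at 6 decimals for exactly this
reason). Sweeps derive per-run seeds as `base + 1000·value_index +
replicate`. The convolution oracle truncates the Poisson visit count where
its tail mass falls below 1e−13 and refuses supports beyond 200,000 states
rather than silently approximating.

Problem sizes: cohorts default to N = 10,000 flowers (the scale at which the
reference summaries are quoted; one cohort simulates in well under a second).
Across-seed acceptance checks use 20 cohorts; sweep tests use the published
grids (λ ∈ {2.5..6.0}, c ∈ {0.5..1.0}, slope ∈ {0.05..0.45}) with 10
replicates where single-run skewness noise would otherwise dominate (sweep
defaults stay at 1 replicate, matching the one-run-per-setting design the
figures reflect).

## What the synthetic "empirical" fixture is

`generate_pseudo_empirical` draws weights from the *same* generative model
under an independent seed. It exists to exercise the two-sample comparison
workflow (file I/O, K-S machinery) when no field data are on disk — passing
a two-sample test against it demonstrates internal consistency only, and
says nothing about agreement with real greenhouse fruit. Real validation
requires observed weights, which users must supply as a one-column CSV to
`strawsim analyze` / `ks_two_sample`.

## Known limitations

- No genotype or environment covariates beyond the single Gaussian residual;
  no nonlinear achene-to-weight curves; no ovule/stigmata ceiling.
- No mechanistic bee behaviour (visit durations, density→λ mapping); λ is a
  dial, not a derived quantity.
- Goodness-of-fit p-values after in-sample parameter estimation are
  anticonservative (above).
- The fitted lognormal's (s, loc, scale) from any single cohort are
  ridge-valued; compare fits by implied moments or likelihood, never by raw
  parameter values.
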
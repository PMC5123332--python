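# Methods

## The problem

Time-series studies of air pollution and health typically assign exposure
from a central-site (CS) monitor, which misses both the spatial variability
of pollutant concentrations across a metropolitan area and the human
activity factors (commuting, infiltration, time indoors) that shape what
people actually breathe. When two pollutants are modelled jointly and their
measurement errors are correlated, the resulting bias in relative-risk (RR)
estimates cannot be reasoned about one pollutant at a time: error in the
copollutant can attenuate, inflate, or spuriously "significate" the other
coefficient.

`copollsim` quantifies these effects by Monte Carlo experiment. Three
exposure metrics per pollutant are related by ZIP-level linear
calibrations; error components are defined as metric differences
(`spatial = AQ − CS`, `population = PE − AQ`, `total = PE − CS`, so spatial
+ population = total identically). "True" exposure is simulated *from* the
error-prone metric, health outcomes are generated under a known effect, and
the health model is refit with and without measurement error.

## Simulation procedure

For a scenario (main pollutant with RR₁ per IQR, copollutant with RR₂,
error type), each iteration:

1. **Calibration realization.** For each ZIP k and each of the two
   pollutants, draw one (θ₁, θ₂) from the asymptotic bivariate normal
   N(θ̂ₖ, σ̂²(XᵀX)⁻¹) of the per-ZIP OLS fit
   `refined = θ₁ + θ₂·unrefined + ε`. Bias is heterogeneous across ZIPs but
   constant across days; draws for the two pollutants are independent (the
   asymptotic normal is per single-pollutant fit). The unrefined predictor
   is CS for spatial/total error and AQ for population error.
2. **Residual realization.** For each (ZIP, day), draw one residual pair
   from N(0, Σ̂ₖ) where Σ̂ₖ is the ZIP's empirical 2×2 covariance of the
   day-paired OLS residuals of the two pollutants — this is what makes the
   two errors correlated.
3. **True exposure.** `true = θ₁ + θ₂·unrefined + ε`; by construction more
   variable than the unrefined series. IQRs are computed from the pooled
   ZIP×day true series of the iteration.
4. **Outcomes.** Poisson counts with
   `log μ = X·B + log RR₁·(true₁/IQR₁) + log RR₂·(true₂/IQR₂)`,
   zero-lag exposure. `X` is the covariate design (below); `B` is estimated
   once per study from baseline counts, mirroring estimation from observed
   data.
5. **Two fits on the same counts.** The "true" fit uses the simulated true
   exposures (per-iteration IQRs); the "noisy" fit uses the unrefined
   exposures standardized by their own IQRs (fixed across iterations).
   Both are maximum-likelihood Poisson regressions.

Summaries over N iterations: mean RR `exp(Σβ̂ₙ/N)`, percent attenuation
`100·(RR₁ − R̄R₁,noisy)/(RR₁ − 1)`, RMSE of β̂ around log RR and the
noisy/true RMSE ratio, rejection proportion at |z| > 1.96 (power for the
main pollutant, type I error for the null copollutant) with binomial SE
√(p(1−p)/N), and 95% CI coverage. The rejection rule defaults to two-sided
(nominal null rate 0.05); a one-sided z > 1.96 rule is available by flag.
Welch's two-sided t-test compares estimate streams across copollutants.
The SE of the mean RR is reported as sd(β̂)/√N; the across-iteration sd is
emitted alongside.

## Health model design

Per (ZIP, day) row: intercept; ZIP indicators; day-of-week and holiday
indicators; per-hospital reporting indicators (each hospital contributes
over one contiguous window); a cubic B-spline in calendar time with
interior knots at the first day of each month (long-term trend and
seasonality); max-temperature indicators per observed integer °C; centered
cubic polynomials in dew point and minimum temperature; season indicators.
Reference levels: first ZIP, Monday, coldest temperature bin, winter.
Exactly aliased columns (e.g. season steps absorbed when the window is
short, an always-on hospital) are detected by a greedy order-respecting
Gram–Schmidt pass and dropped with a log message, keeping earlier blocks.

B-splines were chosen over a truncated-power basis for conditioning; the
span is identical (verified in tests), with dimension n_knots + 3. Natural
boundary constraints are not imposed.

All Poisson fits use iteratively reweighted least squares with the weighted
normal equations solved by Cholesky factorization, relative log-likelihood
tolerance 1e-8, at most 100 iterations, and a linear-predictor clip at ±30
to guard overflow. The implementation agrees with statsmodels GLM to ~1e-6
or better (cross-checked in the test suite); it exists because the Monte
Carlo budget needs thousands of ~10⁴×90 GLM fits, and a Cholesky IRLS is
about eight times faster than the general-purpose SVD path. Iterations
whose fit does not converge are dropped and logged; a scenario with more
than 1% failures is invalid.

## Synthetic data generator

No public exposure or ED-count data accompany this design, so the
generator creates data in which the analysis assumptions hold exactly:

* **CS series**: seasonal cosine plus stationary AR(1) deviations, jointly
  Gaussian across pollutants with a configured correlation; identical
  across ZIPs by definition. Local combustion species (CO, NOx, EC) peak in
  winter, secondary regional species (PM2.5, SO4, O3) in summer.
* **AQ from CS, PE from AQ**: the same linear-calibration-plus-correlated-
  residual mechanism the analysis later estimates and inverts. Local
  species get spatial-stage residual SDs of 50% of their day-to-day SD
  versus 15% for regional species — the premise that central-site
  assignment is far worse for spatially heterogeneous pollutants. The
  population stage applies θ₂ = 0.85 (infiltration-style shrinkage) with
  moderate residual SD for all species.
* **Covariates**: weather is a summer-peaked sinusoid plus noise shared
  across ZIPs; ten fixed holiday dates per year; hospital windows uniform
  over 50–95% of the study period.
* **Baseline counts**: Poisson draws from a known coefficient vector B*
  whose non-intercept entries contribute N(0, 0.03²) to the linear
  predictor per column SD, intercept solved so the mean rate matches the
  configured baseline. The pipeline then re-estimates B from these counts.

Concentrations are not truncated at zero (the linear error model lives on
the raw scale; truncation would distort the covariance structure the
analysis relies on). Negative values are counted and logged.

Default scenario: 15 ZIPs × 730 days × 6 hospitals, baseline rate 2
ED visits per ZIP-day, RR₁ = 1.05 per IQR, RR₂ = 1, N = 200 iterations —
a desk-scale design chosen to preserve near-unit power for the main
pollutant. Concentration levels are order-of-magnitude realistic for a
large southeastern US metro (CO 0.6 ppm, NOx 45 ppb, EC 1.6 µg/m³,
PM2.5 16 µg/m³, SO4 4.5 µg/m³, O3 45 ppb); the split between seasonal
amplitude and day-to-day SD was set so that the identifiable (non-seasonal)
share of exposure variance keeps the main-pollutant z-statistic well above
the 1.96 threshold, per the Fisher-information bound
I(β) ≤ Σμ · Var(x)/IQR(x)², computed analytically. All of it is
user-overridable through the YAML configuration.

What the generator does **not** emulate: real dispersion or population
exposure modelling, spatially structured (non-exchangeable) ZIP effects,
missing monitor days, overdispersed counts, lagged exposure, or
non-Gaussian concentration distributions. Passing tests therefore
demonstrate internal statistical correctness of the machinery — estimator
calibration, error propagation, summary arithmetic — not agreement with
any particular city's empirical error structure.

## Analytic cross-checks used in the tests

In the classical-error limit (θ pinned at (0,1), pure added noise of
variance σ², uncorrelated copollutant) the noisy fit's expected per-IQR
coefficient is β·θ₂·IQR_W/IQR_true, because the truth equals the observed
series plus independent noise and both fits standardize per IQR. With
Gaussian series the attenuation of the mean RR therefore approaches
1 − √(Var(W)/(Var(W)+σ²)) — the square root of the familiar reliability
ratio, a consequence of simulating truth *outward* from the error-prone
metric rather than observing a noisy copy of a fixed truth. The test suite
asserts this form and that attenuation is monotone in the injected error
variance.

## Numerical and design choices

* One (θ₁, θ₂) draw per ZIP per iteration, independent across ZIPs and
  across the two pollutants; residual draws independent across days.
* Listwise deletion of incomplete days per (ZIP, pollutant); residual
  covariance from pairwise-complete day-matched residuals (population
  normalization, so the diagonal equals each fit's mean squared residual).
* Per-iteration substreams: `SeedSequence(master, spawn_key=(5, i, j, e, n))`
  for iteration n of pair (i, j) and error type e; generator stages use
  spawn keys 1–4. Identical master seeds reproduce every table bit for bit;
  interrupted grids resume from per-scenario CSV files.
* Degenerate inputs: all-zero counts raise (infinite intercept); constant
  calibration predictors raise (slope unidentifiable); constant or
  collinear exposure columns are flagged, not raised, by the copollutant
  fit; non-PSD correlation matrices are rejected at configuration time and
  re-checked before each multivariate draw.
* Attenuation is reported as min–max ranges across copollutants for a fixed
  main pollutant in the rendered table; RR figures carry empirical
  2.5th–97.5th percentile bars, with normal-theory bands available in the
  metrics CSV.

## Known limitations

* The scaled-down default (15 ZIPs, rate 2) caps the main-pollutant
  z-statistic near 4.5–5; with N = 200 an occasional single iteration can
  fall below 1.96, so measured power is 1.00 in most runs but can read
  0.995–0.99. Raising `baseline_rate` or `n_zips` in the configuration
  removes this edge effect at proportional cost.
* Power/type-I summaries treat iterations as exchangeable; no
  multiple-testing adjustment is applied across the scenario grid.
* Measurement-error *correction* (regression calibration, SIMEX) is out of
  scope: the package quantifies error impact, it does not repair it.
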
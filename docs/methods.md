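# Methods

## Design

The package implements a time-stratified case-crossover analysis. The case
hour is the clinical onset hour; controls are every other hour in the same
calendar stratum — same year, month, day of week, and hour of day — giving
3 controls when the weekday occurs four times in the month and 4 when it
occurs five times. The stratification is a true partition of the hourly
calendar (the referent relation is symmetric), which matters for the
validity argument below. Matching removes long-term trends, seasonality,
day-of-week and circadian structure from the exposure contrast; because each
patient is their own control, all time-stable individual characteristics
cancel.

## Exposure assignment and trimming

Each patient is matched to the nearest weather station by great-circle
(haversine) distance, Earth radius 6371 km; patients whose nearest station is
farther than 50 km (configurable) are excluded and reported, not erred on.
Ties in distance break to the lexicographically smallest station id. The lag
matrix row for event-hour *t* is (x_t, …, x_{t−L}) read off the station's
hourly series; hours absent from the series are masked.

Hourly extremes are trimmed in two stages on the pooled case-window values
(cases only; controls inherit the same bounds). Stage 1 computes the pooled
1st and 99th percentiles and masks values strictly outside them; stage 2
recomputes, on the survivors, the 1st percentile (the extreme-low contrast
value `x_ext`) and the 99th (the reference `x_ref`). Percentiles use linear
interpolation between order statistics (type 7) throughout; trim counts
depend on that convention. A degenerate pool (`x_ext == x_ref`) raises when
a contrast is requested, not at trim time.

**Survival rule.** An event-hour enters the model only if its entire lag
window is observed and within bounds; a stratum survives if its case row
and at least one control row do. This is stricter than keeping rows with a
small fraction of masked cells and filling them, and it is deliberate: the
selection indicator is then a function of each member's own covariate
vector, so the conditional likelihood restricted to survivors is still
exactly of the matched-set form. Filling trimmed cells from neighbouring
lags was evaluated during development and rejected — the replaced values
are systematically less extreme than the truth, a one-sided measurement
error that materially biased the recovered cumulative log-OR in simulation.
The 25%-missingness tolerance is retained for pollutant windows, which enter
only through backward means.

## Bases and the cross-basis

The exposure basis is a natural cubic spline, df 3 without intercept
(2 internal knots at the 33.3/66.7% quantiles of the trimmed case-window
distribution; boundary knots at its min/max). It is constructed from the
cubic B-spline basis by projecting out the two boundary second-derivative
degrees of freedom (QR of the boundary second-derivative matrix), and is
evaluated beyond the boundary knots by linear continuation of the boundary
value and slope; such contrasts are flagged as extrapolated. The test suite
verifies span equality with the independent truncated-power natural-spline
construction.

The lag basis is a natural cubic spline *with* intercept on [0, L] with
log-spaced internal knots at exp(i·log L/(n+1)). The default is n = 2
internal knots, giving a 4-dimensional lag basis and hence 12 cross-basis
columns per exposure at df 3; the knot count is configurable. Log spacing
concentrates flexibility at short lags where lag-response curves change
fastest.

The cross-basis row for an event-hour is W[(j,k)] = Σ_ℓ B_j(x_{t−ℓ}) C_k(ℓ),
columns ordered exposure-major; this ordering is normative for
serialization. The design stacks [temperature cross-basis | humidity
cross-basis | pollutant 24-h backward means (centred) | optional
interaction]. The interaction block is rank-reduced: the temperature
cross-basis columns multiplied by the centred scalar 24-h mean relative
humidity of the event-hour (12 extra columns, hence a 12-df likelihood-ratio
test). The functional form of this term is an open design choice; the scalar
form keeps the test df interpretable and the fit well conditioned.

## Conditional logistic fit

Each stratum has exactly one case, so the exact 1:M matched-set likelihood
applies with no tie approximations. Newton–Raphson from β = 0 with up to 30
step-halvings per iteration; internally columns are rescaled to unit pooled
within-stratum SD (pure conditioning, mapped back exactly), and steps are
damped to an infinity-norm of 2 in scaled units. Convergence requires the
relative log-likelihood change below `tol` (1e−8) and the maximum absolute
score below `tol × n_strata` — the score is a sum over strata, so its
tolerance carries that scale. Monotone likelihood (separation) is flagged
when the coefficient norm (in design units) exceeds 15 while still growing
by more than 0.5 per iteration with the likelihood still improving; the
covariance is then withheld. Columns constant within every stratum are
rejected by name. The covariance is the inverse observed information at the
optimum. statsmodels' ConditionalLogit is used in the test suite as an
independent cross-check of coefficients, standard errors and likelihood.

## Effects

All contrasts are linear in β: log OR(x, ℓ) = Σ c_{jk} β_{jk} with
c = (B(x) − B(x_ref)) ⊗ C(ℓ); cumulative windows sum the contrast vectors
over lags; standard errors are delta-method (√(cᵀΣc)); CIs use the 1.96
normal quantile. At x = x_ref every effect is exactly OR 1 with zero
variance. Two cumulative window conventions are reported side by side for
each exposure — lag 0–12 h and 0–16 h for temperature, lag 0–6 h and 0–3 h
for humidity — because the source conventions for these windows disagree;
the first listed is used as the primary window and no attempt is made to
adjudicate. Subgroup estimates are obtained by refitting on the subgroup's
strata (case-crossover strata are patient-specific, so subsetting is exact)
and compared with two-sided z-tests on the log-OR scale.

The sensitivity grid refits exactly nine variants, each perturbing one
configuration family: pollutant removal, exposure-spline df 4, maximum lag
36 h and 48 h, extreme-value retention, and contrast percentiles
2.5/5/10/15 versus the fixed 99th-percentile reference. Non-convergent
variants are reported, not fatal.

## Synthetic data

`simulate_weather` produces hourly temperature as mean + annual sinusoid
(peak mid-July, default amplitude 11 °C) + diurnal sinusoid (peak 15:00,
amplitude 4 °C) + stationary AR(1) noise (ρ = 0.95, innovation SD 0.8 °C);
relative humidity as a mean (72%) plus a negative multiple (−1.5 %/°C) of
the temperature anomaly plus noise, clamped to [0, 100]; pollutants as
lognormal AR(1) series calibrated to the observed medians of a subtropical
urban setting. The default annual-mean temperature is 16.8 °C. Identical
configuration and seed reproduce the output bit for bit.

`simulate_onsets` draws case hours by thinning (accept–reject against the
maximum rate) from λ(t) = λ0(t)·exp(Σ_ℓ f(x_{t−ℓ}, ℓ)) with a known surface
f. Candidate hours are restricted to calendar months fully covered by the
series with a complete lag window before the month's first hour, so every
referent of every case is usable. Because the calendar strata partition the
timeline, the distribution of the case's position within its stratum is
exactly the conditional-logit model with linear predictor Σ_ℓ f — the
generator and the estimator meet at the likelihood, which is what makes
parameter recovery a sharp test. Covariates (age, sex, smoking, alcohol,
GCS, hemorrhage location) are drawn from configurable margins and do not
affect the estimand.

What the generator does *not* emulate: spatial interpolation between
stations, pollutant chemistry or co-variation with weather, missing-data
patterns of real networks, reporting delay in onset times, or a seasonal
baseline hazard (λ0 is user-specified, constant by default). Passing tests
therefore demonstrate correctness of the estimation machinery under the
declared generating process, not robustness to those real-data features.

## Validation experiments and problem sizes

`ccdlnm.experiments` contains the simulation studies the test suite runs:

- **Parameter recovery / coverage** — 100 replicates; each simulates a fresh
  two-year single-station climate and 3000 onsets from a surface linear in
  temperature with a lag profile projected into the lag-basis span (so the
  truth is exactly representable and the experiment isolates estimation
  error), then runs the full pipeline and contrasts the full-window
  cumulative log-OR at P1 vs P99 against the truth. Shipped checks: |bias|
  < 0.05, 95% CI coverage within [0.92, 0.97].
- **Null calibration** — 1000 replicates of 1200 matched sets of size 4 with
  real lag structure and a uniformly random case (the exact null). Each
  replicate computes the 12-df interaction LRT and a subgroup z-test between
  two independent halves; both must reject at 3.5–6.5% at α = 0.05. The
  stratum count is chosen for the 12-df LRT's asymptotics: a 36-column fit
  needs this order of strata before the chi-square reference is accurate.
- **Pipeline type-I error** — 1000 replicates of 300 null onsets through the
  complete pipeline, testing the headline 1-df Wald contrast (full-window
  cumulative log-OR at P1 vs P99); the 1-df contrast is used rather than a
  12-df block test because it is the quantity the analysis reports and is
  well calibrated at this stratum count.

## Numerical conventions and degenerate inputs

Type-7 percentiles everywhere; ISO weekday convention in logs; single civil
timezone with no daylight-saving shifts; CSV dialect comma/UTF-8/ISO-8601.
Empty strata lists, all-identical exposure pools, non-hourly series,
multiple cases per stratum, non-nested LRT inputs, and misaligned design
blocks raise with specific messages. Pools under 100 values warn that trim
bounds are unstable.

## Known limitations

Nearest-station assignment only (no kriging); fixed-df bases (no penalized
smoothing); no robust/sandwich variances or frailty terms; no
attributable-fraction machinery. Subgroup refits can be data-hungry: small
subgroups inherit the separation and convergence diagnostics of the main
fit. The two-stage trim makes `x_ext` a boundary-adjacent quantity; with
very small case series its sampling variability is not propagated into the
reported CIs (the contrast values are treated as fixed, as is conventional
for percentile-based contrasts in this literature).
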
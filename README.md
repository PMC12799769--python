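# ccdlnm

Time-stratified case-crossover analysis with distributed lag non-linear
models (DLNMs) for hourly environmental exposures, built for studies of
short-term triggers of acute clinical events — the motivating application is
the effect of extreme low temperature and low relative humidity on the onset
of acute intracerebral hemorrhage (ICH) over lags of 0–24 hours.

## The design and the model

Each patient contributes one **case hour** (symptom onset) and 3–4 **control
hours**: all other occurrences of the same weekday at the same hour of day in
the same month and year. Because every contrast is within-patient and
within-calendar-stratum, time-invariant confounders, seasonality, day-of-week
and circadian structure cancel by design.

Each event-hour *t* receives its backward exposure history
x<sub>t</sub>, x<sub>t−1</sub>, …, x<sub>t−L</sub> (default L = 24 h) from
the nearest weather station within 50 km. The exposure–lag–response surface
is parameterised by a **cross-basis**

&nbsp;&nbsp;&nbsp;&nbsp;f(x, ℓ) = Σ<sub>j,k</sub> β<sub>jk</sub> B<sub>j</sub>(x) C<sub>k</sub>(ℓ),

with natural cubic splines B over the exposure range (df 3) and a natural
cubic spline C with log-spaced knots over the lag axis. The summed tensor
rows enter a **conditional logistic regression** on the matched sets (exact
1:M likelihood, Newton–Raphson with step-halving), optionally adjusted for
24-h mean pollutant concentrations (PM2.5, PM10, SO2, NO2, O3, CO) and a
temperature × humidity interaction tested by likelihood ratio.

Effects are reported as odds ratios contrasting an extreme-low exposure
(1st percentile after two-stage P1/P99 trimming) against the 99th-percentile
reference: lag-specific OR(x, ℓ), cumulative ORs over lag windows (sums of
lag-specific log-ORs, delta-method CIs), full OR surfaces, subgroup z-tests,
and a nine-variant sensitivity grid (pollutant removal; spline df 4; max lag
36/48 h; extreme-value retention; contrast percentiles 2.5/5/10/15).

A first-class synthetic-data module simulates a humid subtropical hourly
climate (annual/diurnal cycles, AR(1) noise, temperature–humidity
anticorrelation, lognormal pollutants) and draws onsets by thinning from a
rate with a *known* exposure–lag–response surface, so every stage of the
pipeline has a parameter-recovery target.

## Worked example

Simulate a two-year study with a known cold effect, fit it, and compare the
estimate against the generating truth:

```sh
ccdlnm recover --seed 3 --n-cases 2000 --out results/demo
```

which prints (numbers from this exact command):

```json
{
  "contrast": {
    "x": 0.3643625230629084,
    "x_ref": 30.611902550950518
  },
  "true_cumulative_log_or": 1.722762170006748,
  "estimated_cumulative_log_or": 1.3842990993434436,
  "se": 0.5690218705737256,
  "or": 3.9920269097404484,
  "ci_low": 1.3087032043873232,
  "ci_high": 12.177152768226417,
  "true_or": 5.599975204742502,
  "covered": true,
  "n_strata": 1717
}
```

Read: the extreme-cold hour (0.36 °C, the 1st percentile) versus the
reference (30.6 °C, the 99th) carries a true cumulative odds ratio of 5.60
over lags 0–24 h; on this single two-year replicate the pipeline estimates
4.0 (95% CI 1.31–12.18), covering the truth. `ccdlnm simulate` writes station/patient CSVs with a truth
sidecar, `ccdlnm fit` runs the full analysis on such CSVs (effects CSV, fit
JSON, exclusion and provenance records), `ccdlnm predict` evaluates saved
fits on exposure–lag grids, and `ccdlnm sensitivity` runs the nine-variant
grid.

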
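# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `floodcohort`.

## Study design

The analysis unit is the *matched stratum*: one flood exposure period (a
maximal run of consecutive days on which a ZIP code meets the exposure
rule) together with two non-flooded control windows from the same ZIP,
covering the same days of the year in different years. Because exposed and
control windows share the ZIP and the calendar position, all time-invariant
ZIP characteristics and the seasonal cycle cancel within a stratum; only
year-to-year differences remain, which the model addresses with a smooth
year term and window means of meteorology and pollution.

Each window contributes `n_lags + 1` observations: lag 0 is the window
itself (variable length, 1–42 days, handled entirely through the
person-time offset), and lag `l ≥ 1` is the `l`-th trailing 7-day week.
The default is 4 lag weeks; the extended secondary analysis uses 12.

### Exposure rule

A ZIP-day is exposed when flooded fraction ≥ 0.5% **or** flooded area ≥ 5
sq mi. Comparisons are inclusive, both thresholds are parameters (for
sensitivity variants), and the rule is evaluated per day with the event
footprint applied to every flooded day (whether the rule should instead be
evaluated once per event footprint is genuinely ambiguous; the per-day
choice is the stricter reading and is exposed through the threshold
parameters). Only floods caused by heavy rain or tropical storms are kept
in the primary analysis. Severity of a multi-event period is the maximum
over its days (moderate < high < extreme) — conservative for the
"high or extreme" stratum; causes and event ids are unions.

### Control selection

Candidate control years are all study years other than the exposure year
in which the shifted window *plus its full lag tail* (`7 * n_lags` days)
stays inside the study window and contains no exposed day for that ZIP.
Requiring a clean tail prevents other floods from contaminating control
lag weeks; `require_clean_tail=False` relaxes the check to the window
itself. From the candidates, the default "nearest-balanced" policy picks
the nearest eligible year before and the nearest after the flood (ties
prefer the earlier year; one-sided fallback when a side is empty), which
is deterministic; a seeded `random` policy exists for sensitivity.
Periods with fewer than two candidates are dropped and logged in the
attrition table, as are periods whose own lag tail leaves the study
window. Later floods inside an *exposed* window's lag tail are kept by
default (intention-to-treat reading); `censor_exposed_tail_floods` drops
such strata instead.

**Feb 29.** Control windows anchor the start month-day (Feb 29 → Feb 28 in
non-leap years) and preserve duration. A window *ending* on Feb 29 instead
anchors its end at Feb 28 and starts one day earlier, so controls also
finish on the last day of February. An interior Feb 29 necessarily slides
the control's end one month-day later — the only duration-preserving
option.

## The model

For observation `i` in stratum `s(i)` with person-time `o_i`:

    log mu_i = alpha_s(i) + log o_i
               + sum_{l=0..L} beta_l * 1[arm = exposed, lag = l]
               + ns(year_i; 2 df) + sum_v ns(xbar_vi; 2 df)
    Var(y_i) = phi * mu_i

- `year_i` is the decimal year at the window midpoint (the smooth year term
  is meant to absorb secular trends; any within-window variation is
  negligible at 2 df over a multi-year span).
- `xbar_vi` are window means of tmax, rhmax, wind, PM2.5, NO2, O3, pooled
  across arms and lags; spline bases are fit once per cause on the full
  analytical dataset, matching the single model fit.
- Natural cubic splines use the truncated-power construction: boundary
  knots at the training min/max, `df - 1` interior knots at equally spaced
  quantiles (df = 2 → the median), zero second derivative at and beyond the
  boundaries, and evaluation of new points against the stored knots.

### Fitting

Conditioning on stratum totals is implemented by exact profiling: for
Poisson data the stratum intercept has the closed form
`alpha_s = log(sum_s y) - log(sum_s exp(x'beta + log o))`, and the Newton
step for `beta` uses the exact profile Hessian — the Schur complement of
the joint information with respect to the intercepts, equal to the
mu-weighted cross-product of the within-stratum weighted-centred design.
This yields point estimates identical to both the conditional-likelihood
and dummy-variable Poisson MLEs (asserted in tests against an independent
generic-optimiser fit) at a cost independent of the number of strata.

Numerical choices: start at `beta = 0`; step-halving on the profile
log-likelihood; convergence when the max absolute coefficient change is
below 1e-10 (cap 100 iterations, non-convergence flagged, never silent);
zero-count strata are dropped before fitting (their conditional likelihood
is constant); rank of the within-stratum centred design is checked up
front with a pivoted QR that names the collinear columns.

Dispersion is Pearson chi-square over `n - p - S` degrees of freedom,
where `S` counts retained stratum intercepts; a floor at 1.0 is available
but off by default. The covariance is `phi` times the inverse profile
information. Effects are `(exp(beta_l) - 1) x 100` with CIs from the
normal quantile `1 - alpha / (2m)`; the Bonferroni family size `m` is an
explicit, logged argument defaulting to the number of lag estimates per
model (5), since the intended family is ambiguous (causes, lags, or both).
The mean effect over lags uses the uniform linear combination on the log
scale (`exp(mean beta_l)`, variance `c'Vc`); the arithmetic mean of
percentage changes is deliberately not the default because percentages do
not average coherently on the rate scale.

### Stratified analyses

Severity (moderate vs high-or-extreme) and season partition whole matched
strata by the exposed period's metadata; warm season is April–September by
the start date (configurable — the dichotomy itself is a convention).
Admission type re-aggregates counts under the filter and re-fits the same
strata. ZIP-level splits (% Black residents, median income, poverty rate)
use the median over *exposed* ZIPs — the analysis population — with an
explicit threshold override. Subcause analyses reuse the pipeline with a
different code→cause mapping plus the ≥ 20 000-admission inclusion filter.

## The synthetic world

The generator emulates the five input tables (ZIP-day exposures,
cause-specific counts, daily covariates, ZIP-year enrolment, ZIP census)
with the downstream model *correctly specified*, so recovery tests have an
unambiguous truth:

- **Counts**: `y ~ Poisson(g * mu)` with `log mu` = log enrolment + log
  baseline rate + seasonal sinusoid (amplitude 0.10 on the log scale — a
  winter/summer swing of ~±10%, typical of all-cause admissions) + linear
  secular trend (0.01 / year) + per-SD covariate effects (tmax 0.02,
  PM2.5 0.01) + the injected lag effect for the day's lag window. The 13
  default causes carry baseline daily rates per 100 000 person-days
  proportioned to the observed cause mix of older-adult inpatient claims
  (circulatory 26.7, respiratory 11.8, ..., skin 1.5), totalling ~85.
- **Overdispersion**: `g` is a gamma frailty with mean 1 and variance
  `dispersion - 1`, shared within (ZIP, week) and across causes, inducing
  realistic within-window correlation. The default is `dispersion = 1`
  (equidispersed): the frailty produces quadratic (NB-type) variance while
  quasi-Poisson models linear inflation, so the correctly-specified
  baseline is the right default for recovery and coverage experiments; the
  frailty mechanism is exercised explicitly in the dispersion tests at
  variances 0, 0.5 and 1.0, where the Pearson dispersion must rise
  monotonically.
- **Covariates**: seasonal sinusoids plus AR(1) noise (lag-1 correlation
  0.7) with persistent ZIP offsets; effects are applied to internally
  standardised values so configured sizes are per-SD.
- **Floods**: events have truncated-geometric durations (mean ~4 days,
  range 1–42), contiguous ZIP blocks, per-ZIP Beta(1.2, 30) flooded
  fractions, severity probabilities (0.56, 0.14, 0.30) and cause
  probabilities (0.81, 0.19) matching the observed census of major US
  flood events. Events within a ZIP are separated by more than the full
  lag tail (resampled on collision) so the injected truth is unambiguous;
  overlapping-flood handling is tested with hand-built fixtures instead.
  Event starts are placed so the lag tail fits inside the window.
- **Enrolment** is ZIP-year (the cadence at which insurer denominators
  exist); day-wise interpolation would be spurious precision. Person-time
  of a window is the day-wise sum of ZIP-year enrolment, so windows
  straddling Dec 31 are exact.

Everything is deterministic given the config seed (independent
`SeedSequence`-derived streams per stage), and a companion table of true
per-lag log rate ratios accompanies every count table.

What the generator does **not** emulate: spatial correlation of floods
with covariates (flood timing is independent of weather), migration or
within-year enrolment churn, cause-specific seasonality differences,
reporting lags, or claim-level record structure. Passing recovery tests
therefore demonstrates the correctness of the machinery under the stated
data-generating process, not robustness to real-data misspecification —
with one caveat worth naming: because control windows match day-of-year,
the residual seasonal drift *across* lag weeks within the 5-week span is
common to exposed and control arms but not explicitly modelled; at the
default amplitude it is an order of magnitude below the sampling error of
the lag estimates.

## Problem sizes

The validation experiments use: a full-scale recovery world of 50 ZIPs ×
17 years × 30 events (~100+ strata); replicate studies (CI coverage,
type-I error) at 12 ZIPs × 7 years × 10 events with 200 seeded replicates
each; oracle-equivalence checks on 20 random fixtures of 3–50 strata; and
dispersion checks on 25 ZIPs × 9 years × 25 events. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping the whole suite quick to run.

## Known limitations

- The conditional model assumes counts are independent across lag windows
  given the stratum; the gamma-frailty world violates this (shared weekly
  shocks), which quasi-Poisson absorbs only on average — coverage under
  strong frailty is approximate.
- ZIP geography is abstracted to zone ids; reconciling billing ZIPs with
  census ZCTA polygons is out of scope (the zonal-aggregation entry point
  accepts any congruent zone/flood grid pair).
- No distributed-lag *nonlinear* structure: lags enter as unconstrained
  indicators by design.
- The `random` control-selection policy samples uniformly; no
  distance-weighted alternative is provided.
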
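# floodcohort

Self-matched cohort analysis of flood exposure and cause-specific
hospitalisation rates.

Severe floods are the most frequent climate-related disaster, and their
health footprint reaches far beyond drownings and injuries: contaminated
standing water, interrupted access to care, and the physical strain of
clean-up all shift hospitalisation patterns for weeks after the water
recedes. `floodcohort` implements the full statistical pipeline for
quantifying those shifts from ZIP-level flood maps and hospitalisation
counts, aimed at environmental epidemiologists and biostatisticians working
with claims-type count data and area-level disaster exposures.

## What it does

1. **Exposure** — classifies a ZIP code and day as flood-exposed when the
   mapped flood covers ≥ 0.5% of the ZIP's surface area *or* ≥ 5 square
   miles of it (both thresholds configurable), aggregates gridded flood
   extents to zones when needed, collapses exposed days into maximal
   consecutive-day *exposure periods*, and restricts to floods caused by
   heavy rain or tropical storms.
2. **Matching** — pairs each exposure period with two non-flooded control
   windows in the same ZIP and the same days of the year, in the nearest
   eligible years before and after the flood. Conditioning on these matched
   strata removes time-invariant ZIP confounding and seasonality by design.
3. **Assembly** — expands each stratum into one row per (arm, lag): lag 0 is
   the window itself, lags 1..L the trailing 7-day weeks (L = 4 by default,
   12 for the extended secondary analysis), with outcome counts, log
   person-time offsets from ZIP-year enrolment, and window means of
   temperature, humidity, wind, PM2.5, NO2 and O3.
4. **Model** — fits a conditional quasi-Poisson distributed-lag model. For
   count `y_i` in stratum `s(i)` with offset `o_i`:

       y_i ~ quasiPoisson(mu_i),   Var(y_i) = phi * mu_i
       log mu_i = alpha_s(i) + log o_i + sum_l beta_l * 1[exposed, lag l]
                  + ns(year; 2 df) + sum_v ns(xbar_v; 2 df)

   Stratum intercepts `alpha_s` are profiled out in closed form inside each
   Newton step (identical point estimates to the dummy-variable and
   conditional Poisson MLE), `phi` is the Pearson dispersion with
   `n - p - S` degrees of freedom, and effects are reported as relative
   percentage changes `(RR - 1) x 100 = (exp(beta_l) - 1) x 100` with
   Bonferroni-corrected 95% CIs (family size `m` always explicit).
5. **Stratified analyses** — severity (moderate vs high-or-extreme), season
   (warm vs cold), admission type (emergency vs non-emergency), and
   ZIP-level median splits on % Black residents, median income, and poverty
   rate; plus a ≥ 20 000-admission inclusion filter for subcause analyses.
6. **Simulation** — a synthetic-world generator (ZIPs, enrolment, daily
   covariates, flood events, hospitalisation counts) with *known* injected
   lag effects and optional gamma-frailty overdispersion, so the entire
   pipeline is validated by parameter recovery without any restricted data.

## Worked example

```python
import datetime as dt
import numpy as np
import floodcohort as fc

cfg = fc.SimConfig(
    n_zips=20, date_start=dt.date(2000, 1, 1), date_end=dt.date(2008, 12, 31),
    n_events=15, causes={"skin": 8.0},
    lag_effects={"skin": [np.log(1.5), 0.25, 0.15, 0.08, 0.04]},
    seed=3,
)
world, exposures, counts, truth = fc.simulate_tables(cfg)
flagged = fc.exposed_zip_days(exposures)
periods = fc.filter_periods_by_cause(fc.build_exposure_periods(flagged))
strata, attrition = fc.build_strata(
    periods, fc.exposure_calendar(flagged),
    fc.MatchConfig(cfg.date_start, cfg.date_end),
)
dataset = fc.build_analytical_dataset(
    strata, counts, world.covariates, world.population, "skin"
)
fit = fc.fit_conditional_quasipoisson(dataset)
effects = fc.lag_effects(fit, alpha=0.05, m=5) + [fc.mean_effect(fit, alpha=0.05, m=5)]
print(f"{len(periods)} exposure periods, {len(strata)} matched strata, "
      f"dispersion = {fit.dispersion:.2f}")
print(fc.effects_table(effects)[["lag", "pct_change", "ci_low", "ci_high"]]
      .round(1).to_string(index=False))
```

prints

```
58 exposure periods, 58 matched strata, dispersion = 0.96
 lag  pct_change  ci_low  ci_high
   0        56.3    16.4    109.9
   1        16.0    -9.9     49.4
   2        10.2   -15.0     42.8
   3         0.7   -23.1     31.7
   4       -14.0   -35.3     14.3
mean        11.6    -3.6     29.2
```

The simulation injected a +50% rate increase during exposure
(`log 1.5 ≈ 0.41`) decaying over four lag weeks; the fitted lag-0 estimate
of +56.3% (Bonferroni-corrected 95% CI 16.4 to 109.9, m = 5) recovers it
within sampling error, the dispersion estimate sits at 1 as expected for
equidispersed counts, and the "mean" row averages the five lag coefficients
on the log scale before transforming back to a percentage.

The same pipeline is scriptable from a shell (`floodcohort simulate`,
`expose`, `match`, `assemble`, `fit`, `stratified`, `report`); each
subcommand exchanges plain CSV tables.

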
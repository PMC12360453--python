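"""Synthetic world generator for the flood–hospitalisation pipeline.

Builds a fully self-contained study world — ZIP codes with enrolled
populations, daily meteorology/pollution covariates, ZIP-level census
indicators, flood events, and cause-specific hospitalisation counts — with
*known* injected flood effects, so every downstream stage (exposure
classification, matching, assembly, model fitting, stratification) can be
validated by parameter recovery without any external data.

The count model is chosen so that the downstream conditional quasi-Poisson
distributed-lag model is correctly specified: for ZIP :math:`z`, day
:math:`t`, cause :math:`c`,

.. math::

    y_{ztc} \\sim \\mathrm{Poisson}(g_{zw(t)} \\, \\mu_{ztc}),\\qquad
    \\log \\mu_{ztc} = \\log(\\mathrm{pop}_{z,\\mathrm{yr}(t)})
    + \\log(\\lambda_c/10^5) + A\\sin(2\\pi\\,\\mathrm{doy}(t)/365.25)
    + \\gamma\\,(\\mathrm{yr}(t)-\\bar{\\mathrm{yr}})
    + \\textstyle\\sum_v \\theta_v \\tilde{x}_{ztv}
    + \\beta_{c,\\ell(z,t)},

where :math:`\\beta_{c,\\ell}` is the injected log rate ratio for lag window
:math:`\\ell` (0 = the exposure period itself, :math:`\\ell\\ge 1` the
:math:`\\ell`-th trailing week), :math:`\\tilde{x}` are covariates
standardised to unit SD, and :math:`g_{zw}` is a gamma frailty with mean 1
and variance (dispersion − 1) shared within each (ZIP, week) to induce
overdispersion. A companion table of the true per-lag log rate ratios is
emitted for recovery testing.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from . import exposure as expo

#: Covariate variables carried by the world (GridMET-style meteorology plus
#: SEDAC-style pollutants), with (annual mean, seasonal amplitude, seasonal
#: phase in days, AR(1) innovation SD).
COVARIATE_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "tmax": (18.0, 12.0, 200.0, 3.0),
    "rhmax": (80.0, 8.0, 20.0, 6.0),
    "wind": (4.5, 1.0, 30.0, 1.2),
    "pm25": (9.0, 2.5, 210.0, 2.0),
    "no2": (16.0, 4.0, 20.0, 3.0),
    "o3": (38.0, 8.0, 200.0, 4.0),
}
COVARIATE_VARS = tuple(COVARIATE_PROFILES)

#: Lag-1 autocorrelation of the covariate noise.
AR1_RHO = 0.7

#: The 13 retained level-1 causes of hospitalisation with baseline daily
#: rates per 100 000 person-days, proportioned to the cause mix observed in
#: older-adult inpatient claims (circulatory ~31%, respiratory ~14%, ...),
#: totalling ~85 admissions per 100 000 person-days.
DEFAULT_CAUSE_RATES: dict[str, float] = {
    "circulatory": 26.7,
    "respiratory": 11.8,
    "digestive": 9.2,
    "injury_poisoning": 8.1,
    "genitourinary": 5.5,
    "musculoskeletal": 5.3,
    "neoplasms": 4.7,
    "infectious_parasitic": 4.0,
    "endocrine": 3.6,
    "nervous_system": 3.3,
    "mental_illness": 3.2,
    "skin": 1.5,
    "blood": 1.4,
}

ADMISSION_TYPES = ("emergency", "non_emergency")
#: Share of admissions arriving through the emergency department.
EMERGENCY_SHARE = 0.55

#: Severity and flood-cause sampling probabilities for generated events,
#: matching the observed census of major US flood events (56% moderate,
#: 14% high, 30% extreme; 81% heavy rain vs 19% tropical storm).
SEVERITY_PROBS = (0.56, 0.14, 0.30)
FLOOD_CAUSE_PROBS = (0.81, 0.19)
EVENT_CAUSES = ("heavy_rain", "tropical_storm")

#: Flood-event durations are geometric (mean ~4 days) truncated to the
#: observed 1–42 day range.
DURATION_GEOM_P = 0.25
DURATION_MAX = 42


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study world.

    Defaults mirror the study conditions: a 17-year window (2000–16),
    72 distinct flood events, 13 causes of hospitalisation, 4 lag weeks.
    """

    n_zips: int = 50
    date_start: dt.date = dt.date(2000, 1, 1)
    date_end: dt.date = dt.date(2016, 12, 31)
    n_events: int = 72
    causes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CAUSE_RATES))
    lag_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    n_lags: int = 4
    seasonal_amplitude: float = 0.10
    year_trend_slope: float = 0.01
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"tmax": 0.02, "pm25": 0.01}
    )
    dispersion: float = 1.0
    population_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_zips <= 0:
            raise ConfigError("n_zips must be a positive integer")
        if self.date_end <= self.date_start:
            raise ConfigError("date_end must be after date_start")
        if self.n_events < 0:
            raise ConfigError("n_events must be non-negative")
        if not self.causes:
            raise ConfigError("causes must be non-empty")
        for c, r in self.causes.items():
            if r <= 0:
                raise ConfigError(f"causes: baseline rate for {c!r} must be > 0")
        if self.n_lags < 0:
            raise ConfigError("n_lags must be non-negative")
        for c, v in self.lag_effects.items():
            if c not in self.causes:
                raise ConfigError(f"lag_effects: unknown cause {c!r}")
            if len(v) != self.n_lags + 1:
                raise ConfigError(
                    f"lag_effects: vector for {c!r} must have length n_lags+1 = {self.n_lags + 1}"
                )
        for v in self.covariate_effect_sizes:
            if v not in COVARIATE_PROFILES:
                raise ConfigError(f"covariate_effect_sizes: unknown covariate {v!r}")
        if self.dispersion < 1:
            raise ConfigError("dispersion must be >= 1")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ConfigError("population_range must satisfy 0 < min <= max")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.date_start, self.date_end, freq="D")

    @property
    def years(self) -> range:
        return range(self.date_start.year, self.date_end.year + 1)


@dataclass
class SyntheticWorld:
    """The generated study world (everything except floods and outcomes)."""

    zip_ids: list[str]
    zip_area_sqmi: pd.Series  # index: zip
    population: pd.DataFrame  # columns zip, year, enrollees
    covariates: pd.DataFrame  # columns zip, date, tmax, rhmax, wind, pm25, no2, o3
    census: pd.DataFrame  # columns zip, pct_black, median_income, poverty_rate
    config: SimConfig

    def population_lookup(self) -> dict[tuple[str, int], int]:
        return {
            (z, int(y)): int(n)
            for z, y, n in zip(
                self.population["zip"], self.population["year"], self.population["enrollees"]
            )
        }


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_world(config: SimConfig) -> SyntheticWorld:
    """Generate ZIPs, populations, daily covariates and census indicators.

    Deterministic given ``config.seed``. Covariates are seasonal sinusoids
    plus AR(1) noise (lag-1 correlation 0.7); census covariates are drawn
    once per ZIP.
    """
    config.validate()
    rng_pop, rng_cov, rng_census, _, _ = _rngs(config.seed, 5)

    zip_ids = [f"Z{i:05d}" for i in range(1, config.n_zips + 1)]
    dates = config.dates
    n_days = len(dates)
    doy = dates.dayofyear.to_numpy()

    # ZIP surface areas (sq mi), lognormal around ~80 sq mi
    area = pd.Series(
        np.round(np.exp(rng_pop.normal(math.log(80.0), 0.6, config.n_zips)), 2),
        index=zip_ids,
        name="area_sqmi",
    )

    # population: per-ZIP base with a small multiplicative yearly drift
    lo, hi = config.population_range
    base = rng_pop.integers(lo, hi + 1, config.n_zips).astype(float)
    growth = rng_pop.normal(0.01, 0.01, config.n_zips)
    years = np.array(list(config.years))
    pop = np.rint(base[:, None] * (1.0 + growth[:, None]) ** (years[None, :] - years[0]))
    pop = np.maximum(pop, 1.0).astype(int)
    population = pd.DataFrame(
        {
            "zip": np.repeat(zip_ids, len(years)),
            "year": np.tile(years, config.n_zips),
            "enrollees": pop.ravel(),
        }
    )

    # covariates: mean + seasonal sinusoid + AR(1) noise, per ZIP and variable
    cov_data: dict[str, np.ndarray] = {}
    for var, (mean, amp, phase, sd) in COVARIATE_PROFILES.items():
        seasonal = mean + amp * np.sin(2 * np.pi * (doy - phase) / 365.25)
        eps = rng_cov.normal(0.0, sd, (n_days, config.n_zips))
        noise = signal.lfilter([1.0], [1.0, -AR1_RHO], eps, axis=0)
        # ZIP-specific level offsets so ZIPs differ persistently
        offsets = rng_cov.normal(0.0, sd / 2.0, config.n_zips)
        cov_data[var] = (seasonal[:, None] + noise + offsets[None, :]).T.ravel()

    covariates = pd.DataFrame(
        {
            "zip": np.repeat(zip_ids, n_days),
            "date": np.tile(dates.values, config.n_zips),
            **cov_data,
        }
    )

    census = pd.DataFrame(
        {
            "zip": zip_ids,
            "pct_black": rng_census.beta(2.0, 8.0, config.n_zips),
            "median_income": np.round(
                np.clip(rng_census.normal(60_000, 15_000, config.n_zips), 25_000, None), 0
            ),
            "poverty_rate": rng_census.beta(2.0, 10.0, config.n_zips),
        }
    )

    return SyntheticWorld(
        zip_ids=zip_ids,
        zip_area_sqmi=area,
        population=population,
        covariates=covariates,
        census=census,
        config=config,
    )


# ---------------------------------------------------------------------------
# Flood events
# ---------------------------------------------------------------------------

def _sample_duration(rng: np.random.Generator) -> int:
    """Geometric event duration truncated to [1, 42] days (resampled)."""
    while True:
        d = int(rng.geometric(DURATION_GEOM_P))
        if 1 <= d <= DURATION_MAX:
            return d


def generate_flood_events(world: SyntheticWorld, config: SimConfig) -> pd.DataFrame:
    """Sample flood events and expand them into a ZIP-day exposure table.

    Each event has a start date, a truncated-geometric duration in [1, 42]
    days, a contiguous block of ZIPs, per-ZIP flooded fractions, a severity
    label (moderate/high/extreme with probabilities 0.56/0.14/0.30) and a
    flood cause (heavy rain 0.81 / tropical storm 0.19). Events within a ZIP
    are separated by more than the full lag tail (n_lags weeks) so injected
    lag effects are unambiguous; colliding draws are resampled. The event
    footprint (per-ZIP fraction) is applied to every flooded day.

    Returns a DataFrame with columns ``zip, date, event_id, frac_flooded,
    area_flooded_sqmi, severity, cause``.
    """
    config.validate()
    (rng,) = _rngs(config.seed ^ 0x5EED, 1)
    n_days = (config.date_end - config.date_start).days + 1
    tail = 7 * config.n_lags
    occupied: dict[str, list[tuple[int, int]]] = {z: [] for z in world.zip_ids}

    rows: list[tuple] = []
    for event_idx in range(config.n_events):
        event_id = f"E{event_idx + 1:03d}"
        severity = rng.choice(expo.SEVERITIES, p=SEVERITY_PROBS)
        cause = rng.choice(EVENT_CAUSES, p=FLOOD_CAUSE_PROBS)
        for _attempt in range(1000):
            duration = _sample_duration(rng)
            max_start = n_days - duration - tail
            if max_start < 1:
                raise ConfigError("study window too short for events with lag tail")
            start_off = int(rng.integers(0, max_start))
            n_block = int(min(1 + rng.poisson(3.0), config.n_zips))
            block_start = int(rng.integers(0, config.n_zips - n_block + 1))
            zips = world.zip_ids[block_start : block_start + n_block]
            lo = start_off - tail - 1
            hi = start_off + duration - 1 + tail + 1
            if any(
                s <= hi and e >= lo
                for z in zips
                for (s, e) in occupied[z]
            ):
                continue  # collision: resample event placement
            break
        else:  # pragma: no cover - pathological config
            raise ConfigError("could not place flood events without overlap")
        for z in zips:
            occupied[z].append((start_off, start_off + duration - 1))
        fracs = rng.beta(1.2, 30.0, len(zips)) + 1e-6
        start_date = config.date_start + dt.timedelta(days=start_off)
        for z, frac in zip(zips, fracs):
            area = frac * float(world.zip_area_sqmi[z])
            for d in range(duration):
                rows.append(
                    (z, start_date + dt.timedelta(days=d), event_id, frac, area, severity, cause)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "zip",
            "date",
            "event_id",
            "frac_flooded",
            "area_flooded_sqmi",
            "severity",
            "cause",
        ],
    )


# ---------------------------------------------------------------------------
# Hospitalisation counts
# ---------------------------------------------------------------------------

def _lag_label_array(
    periods: Sequence[expo.ExposurePeriod],
    zip_index: Mapping[str, int],
    date_start: dt.date,
    n_days: int,
    n_lags: int,
) -> np.ndarray:
    """Integer array (zip, day) of lag-window labels: -1 none, 0..n_lags."""
    lab = np.full((len(zip_index), n_days), -1, dtype=np.int8)
    for p in periods:
        zi = zip_index[p.zip]
        s = (p.start - date_start).days
        e = (p.end - date_start).days
        lab[zi, s : e + 1] = 0
        for l in range(1, n_lags + 1):
            ws = e + 7 * (l - 1) + 1
            we = min(e + 7 * l, n_days - 1)
            if ws < n_days:
                lab[zi, ws : we + 1] = l
    return lab


def generate_hospitalizations(
    world: SyntheticWorld,
    exposures: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily cause-specific hospitalisation counts.

    Flood effects are injected on the ZIP-days that the exposure module's
    classification rule marks as exposed, and on their trailing lag weeks.
    Returns ``(counts, truth)``: a long count table (zip, date, cause,
    admission_type, count; zero cells omitted) and the table of true per-lag
    log rate ratios.
    """
    config.validate()
    rng_g, rng_y, rng_adm = _rngs(config.seed ^ 0xC0DE, 3)

    dates = config.dates
    n_days = len(dates)
    d0, d1 = config.date_start, config.date_end
    if len(exposures):
        ex_dates = pd.to_datetime(exposures["date"])
        if (ex_dates.min().date() < d0) or (ex_dates.max().date() > d1):
            raise ConfigError("exposure days fall outside the study window")

    zip_index = {z: i for i, z in enumerate(world.zip_ids)}
    nz = len(world.zip_ids)

    # exposed ZIP-days via the exposure rule, collapsed into periods
    flagged = expo.exposed_zip_days(exposures) if len(exposures) else exposures
    periods = expo.build_exposure_periods(flagged) if len(flagged) else []
    lag_lab = _lag_label_array(periods, zip_index, d0, n_days, config.n_lags)

    # daily population per zip (zip-year resolution)
    years = np.array(list(config.years))
    year_of_day = dates.year.to_numpy()
    pop_tbl = world.population.pivot(index="zip", columns="year", values="enrollees")
    pop_mat = pop_tbl.loc[world.zip_ids, years].to_numpy(dtype=float)
    year_col = np.searchsorted(years, year_of_day)
    pop_day = pop_mat[:, year_col]  # (nz, n_days)

    # covariate effect term, standardised per variable across the whole world
    cov_term = np.zeros((nz, n_days))
    if config.covariate_effect_sizes:
        cov_wide = world.covariates
        for var, eff in config.covariate_effect_sizes.items():
            x = cov_wide[var].to_numpy().reshape(nz, n_days)
            z = (x - x.mean()) / x.std()
            cov_term += eff * z

    doy = dates.dayofyear.to_numpy()
    season = config.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
    year_frac = year_of_day + (doy - 0.5) / 365.25
    trend = config.year_trend_slope * (year_frac - year_frac.mean())

    # gamma frailty shared within (zip, week) and across causes
    week_idx = np.arange(n_days) // 7
    n_weeks = int(week_idx[-1]) + 1
    if config.dispersion > 1.0:
        v = config.dispersion - 1.0
        g_zw = rng_g.gamma(1.0 / v, v, (nz, n_weeks))
    else:
        g_zw = np.ones((nz, n_weeks))
    g = g_zw[:, week_idx]

    frames = []
    for cause, rate in config.causes.items():
        log_mu = (
            np.log(pop_day)
            + math.log(rate / 1e5)
            + season[None, :]
            + trend[None, :]
            + cov_term
        )
        betas = np.asarray(
            config.lag_effects.get(cause, np.zeros(config.n_lags + 1)), dtype=float
        )
        effect = np.where(lag_lab >= 0, betas[np.maximum(lag_lab, 0)], 0.0)
        mu = np.exp(log_mu + effect)
        counts = rng_y.poisson(g * mu)
        zi, di = np.nonzero(counts)
        if len(zi) == 0:
            continue
        total = counts[zi, di]
        emerg = rng_adm.binomial(total, EMERGENCY_SHARE)
        frames.append(
            pd.DataFrame(
                {
                    "zip": np.asarray(world.zip_ids)[zi],
                    "date": dates.values[di],
                    "cause": cause,
                    "admission_type": "emergency",
                    "count": emerg,
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "zip": np.asarray(world.zip_ids)[zi],
                    "date": dates.values[di],
                    "cause": cause,
                    "admission_type": "non_emergency",
                    "count": total - emerg,
                }
            )
        )

    counts_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["zip", "date", "cause", "admission_type", "count"])
    )
    counts_df = counts_df[counts_df["count"] > 0].reset_index(drop=True)

    truth = pd.DataFrame(
        [
            (cause, l, float(np.asarray(config.lag_effects.get(cause, np.zeros(config.n_lags + 1)))[l]))
            for cause in config.causes
            for l in range(config.n_lags + 1)
        ],
        columns=["cause", "lag", "true_log_rr"],
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# Dataset-level generator (for fitter validation)
# ---------------------------------------------------------------------------

def random_matched_dataset(
    rng: np.random.Generator,
    n_strata: int = 10,
    n_lags: int = 4,
    n_extra: int = 2,
    beta_scale: float = 0.3,
):
    """A random matched-design dataset drawn directly from the count model.

    Skips the geography and produces rows in the matched layout (3 arms x
    (n_lags+1) lags per stratum) with exposure-by-lag indicators,
    ``n_extra`` continuous covariate columns, random person-time offsets and
    Poisson counts under a random coefficient vector. Returns
    ``(AnalyticalDataset, true_beta)``; used to validate the conditional
    fitter against independent oracles.
    """
    from .assemble import AnalyticalDataset

    arms = ["exposed", "control_1", "control_2"]
    p = n_lags + 1 + n_extra
    beta = rng.normal(0.0, beta_scale, p)
    rec, sidx, Xr = [], [], []
    for s in range(n_strata):
        alpha = rng.normal(-7.5, 0.4)
        base_cov = rng.normal(0.0, 1.0, n_extra)
        for arm in arms:
            for lag in range(n_lags + 1):
                x = np.zeros(p)
                if arm == "exposed":
                    x[lag] = 1.0
                x[n_lags + 1 :] = base_cov + rng.normal(0.0, 0.5, n_extra)
                off = float(rng.uniform(5_000, 40_000))
                y = rng.poisson(np.exp(alpha + np.log(off) + x @ beta))
                rec.append(
                    {
                        "stratum_id": f"S{s:03d}",
                        "zip": f"Z{s:03d}",
                        "arm": arm,
                        "lag": lag,
                        "cause": "synthetic",
                        "count": int(y),
                        "person_days": off,
                        "year_frac": 2000.0,
                    }
                )
                sidx.append(s)
                Xr.append(x)
    rows = pd.DataFrame(rec)
    X = np.asarray(Xr)
    ds = AnalyticalDataset(
        rows=rows,
        X=X,
        y=rows["count"].to_numpy(dtype=float),
        log_offset=np.log(rows["person_days"].to_numpy(dtype=float)),
        stratum_index=np.asarray(sidx, dtype=np.int64),
        stratum_ids=[f"S{s:03d}" for s in range(n_strata)],
        columns=[f"lag{l}" for l in range(n_lags + 1)]
        + [f"x{j}" for j in range(n_extra)],
        spline_bases={},
        cause="synthetic",
        n_lags=n_lags,
    )
    return ds, beta


# ---------------------------------------------------------------------------
# Optional grid writer (to exercise zonal aggregation)
# ---------------------------------------------------------------------------

def synthetic_flood_grid(
    n_zones: int = 6,
    zone_cells: int = 100,
    flood_prob: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small synthetic (flood extent, zone map) grid pair for zonal tests.

    Zones are horizontal bands of ``zone_cells`` cells; flood cells are
    Bernoulli(``flood_prob``).
    """
    rng = np.random.default_rng(seed)
    zones = np.repeat(np.arange(n_zones), zone_cells).reshape(n_zones, zone_cells)
    flood = (rng.random(zones.shape) < flood_prob).astype(np.uint8)
    return flood, zones


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------

def simulate_tables(config: SimConfig):
    """Run the full generator; returns (world, exposures, counts, truth)."""
    world = generate_world(config)
    exposures = generate_flood_events(world, config)
    counts, truth = generate_hospitalizations(world, exposures, config)
    return world, exposures, counts, truth


def write_tables(
    world: SyntheticWorld,
    exposures: pd.DataFrame,
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir,
) -> dict[str, Path]:
    """Write the five input CSVs plus the truth table to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    ex = exposures.copy()
    if len(ex):
        ex["date"] = pd.to_datetime(ex["date"]).dt.date
    _w("exposures", ex)
    ct = counts.copy()
    if len(ct):
        ct["date"] = pd.to_datetime(ct["date"]).dt.date
    _w("counts", ct)
    cov = world.covariates.copy()
    cov["date"] = pd.to_datetime(cov["date"]).dt.date
    _w("covariates", cov)
    _w("population", world.population)
    _w("census", world.census)
    _w("truth", truth)
    return paths
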
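"""Synthetic-world generator: determinism, calendars, rates, effect injection."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import floodcohort as fc
from floodcohort.simulate import (
    ConfigError,
    DURATION_MAX,
    SEVERITY_PROBS,
    _sample_duration,
    generate_flood_events,
    generate_hospitalizations,
    generate_world,
    synthetic_flood_grid,
)


def small_config(**kw):
    base = dict(
        n_zips=6,
        date_start=dt.date(2000, 1, 1),
        date_end=dt.date(2003, 12, 31),
        n_events=4,
        causes={"skin": 10.0},
        seed=5,
    )
    base.update(kw)
    return fc.SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(n_zips=0), "n_zips"),
            (dict(date_end=dt.date(1999, 1, 1)), "date_end"),
            (dict(causes={"skin": 0.0}), "baseline rate"),
            (dict(dispersion=0.5), "dispersion"),
            (dict(lag_effects={"skin": [0.0, 0.0]}), "lag_effects"),
            (dict(population_range=(0, 10)), "population_range"),
        ],
    )
    def test_invalid_config_names_field(self, kw, field):
        with pytest.raises(ConfigError, match=field):
            generate_world(small_config(**kw))


class TestWorldGeneration:
    def test_same_seed_reproduces_world_exactly(self):
        w1 = generate_world(small_config())
        w2 = generate_world(small_config())
        assert w1.zip_ids == w2.zip_ids
        pd.testing.assert_frame_equal(w1.covariates, w2.covariates)
        pd.testing.assert_frame_equal(w1.population, w2.population)
        pd.testing.assert_frame_equal(w1.census, w2.census)

    def test_full_window_covariate_record_count(self):
        # 2000-01-01..2016-12-31 is 6210 calendar days by direct enumeration
        cfg = fc.SimConfig(n_zips=2, causes={"skin": 5.0}, n_events=0)
        world = generate_world(cfg)
        assert len(world.covariates) == 2 * 6210
        per_zip = world.covariates.groupby("zip")["date"].nunique()
        assert (per_zip == 6210).all()

    def test_world_invariants(self):
        world = generate_world(small_config())
        assert (world.population["enrollees"] > 0).all()
        assert world.census["pct_black"].between(0, 1).all()
        assert world.covariates[["tmax", "rhmax", "wind", "pm25", "no2", "o3"]].notna().all().all()


class TestFloodEvents:
    def test_durations_within_observed_range(self):
        rng = np.random.default_rng(0)
        durs = [_sample_duration(rng) for _ in range(5000)]
        assert min(durs) >= 1 and max(durs) <= DURATION_MAX

    def test_no_events_gives_empty_table(self):
        cfg = small_config(n_events=0)
        assert len(generate_flood_events(generate_world(cfg), cfg)) == 0

    def test_severity_shares_match_configured_probabilities(self):
        # sampler distribution at n=10000 draws
        rng = np.random.default_rng(1)
        sev = rng.choice(["moderate", "high", "extreme"], p=SEVERITY_PROBS, size=10_000)
        share = (sev == "moderate").mean()
        se = np.sqrt(SEVERITY_PROBS[0] * (1 - SEVERITY_PROBS[0]) / len(sev))
        assert abs(share - SEVERITY_PROBS[0]) < 3 * se
        # and through the generator: one severity/cause label per event
        cfg = fc.SimConfig(
            n_zips=40,
            date_start=dt.date(2000, 1, 1),
            date_end=dt.date(2016, 12, 31),
            n_events=300,
            causes={"skin": 5.0},
            seed=1,
        )
        events = generate_flood_events(generate_world(cfg), cfg)
        per_event = events.groupby("event_id")[["severity", "cause"]].nunique()
        assert (per_event == 1).all().all()
        gen_share = (events.groupby("event_id")["severity"].first() == "moderate").mean()
        assert abs(gen_share - SEVERITY_PROBS[0]) < 3 * np.sqrt(0.56 * 0.44 / 300)

    def test_events_never_overlap_within_zip(self):
        cfg = small_config(n_events=12, seed=9)
        events = generate_flood_events(generate_world(cfg), cfg)
        dup = events.duplicated(subset=["zip", "date"])
        assert not dup.any()

    def test_frac_area_invariant(self):
        cfg = small_config(n_events=8)
        events = generate_flood_events(generate_world(cfg), cfg)
        assert ((events["frac_flooded"] > 0) == (events["area_flooded_sqmi"] > 0)).all()
        assert events["frac_flooded"].between(0, 1).all()


class TestHospitalizations:
    def test_equidispersed_counts_under_poisson_truth(self):
        # zero effects, dispersion 1: variance/mean ratio of cell counts ~ 1.
        # Hold rate structure flat so cells are iid Poisson.
        cfg = fc.SimConfig(
            n_zips=40,
            date_start=dt.date(2000, 1, 1),
            date_end=dt.date(2007, 12, 31),
            n_events=0,
            causes={"skin": 30.0},
            seasonal_amplitude=0.0,
            year_trend_slope=0.0,
            covariate_effect_sizes={},
            population_range=(2000, 2000),
            seed=3,
        )
        world = generate_world(cfg)
        counts, _ = generate_hospitalizations(world, pd.DataFrame(), cfg)
        # re-densify: population growth makes means drift; restrict to year 2000
        y2000 = counts[pd.to_datetime(counts["date"]).dt.year == 2000]
        cell = y2000.groupby(["zip", "date"])["count"].sum()
        n_cells = 40 * 366
        total = cell.sum()
        mean = total / n_cells
        var = (cell**2).sum() / n_cells - mean**2
        assert var / mean == pytest.approx(1.0, abs=0.05)

    def test_injected_lag0_effect_recovered_in_raw_rates(self):
        effect = np.log(1.5)
        cfg = fc.SimConfig(
            n_zips=30,
            date_start=dt.date(2000, 1, 1),
            date_end=dt.date(2009, 12, 31),
            n_events=60,
            causes={"skin": 40.0},
            lag_effects={"skin": [effect, 0, 0, 0, 0]},
            seasonal_amplitude=0.0,
            year_trend_slope=0.0,
            covariate_effect_sizes={},
            population_range=(3000, 3000),
            seed=8,
        )
        world = generate_world(cfg)
        events = generate_flood_events(world, cfg)
        counts, truth = generate_hospitalizations(world, events, cfg)
        flagged = fc.exposed_zip_days(events)
        exposed_keys = set(zip(flagged["zip"], pd.to_datetime(flagged["date"]).dt.date))
        counts["key"] = list(zip(counts["zip"], pd.to_datetime(counts["date"]).dt.date))
        exposed_total = counts.loc[counts["key"].isin(exposed_keys), "count"].sum()
        n_exposed_days = len(exposed_keys)
        n_total_days = cfg.n_zips * len(cfg.dates)
        baseline_total = counts["count"].sum() - exposed_total
        rate_exposed = exposed_total / n_exposed_days
        rate_base = baseline_total / (n_total_days - n_exposed_days)
        # lag weeks 1-4 carry no effect here, so they sit in the baseline pool
        assert rate_exposed / rate_base == pytest.approx(1.5, rel=0.08)
        assert truth.loc[truth["lag"] == 0, "true_log_rr"].iloc[0] == pytest.approx(effect)

    def test_expected_counts_scale_with_population(self):
        lo = small_config(population_range=(1000, 1000), n_events=0, seed=21,
                          causes={"skin": 100.0})
        hi = small_config(population_range=(2000, 2000), n_events=0, seed=21,
                          causes={"skin": 100.0})
        c_lo, _ = generate_hospitalizations(generate_world(lo), pd.DataFrame(), lo)
        c_hi, _ = generate_hospitalizations(generate_world(hi), pd.DataFrame(), hi)
        ratio = c_hi["count"].sum() / c_lo["count"].sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_exposures_outside_window_rejected(self):
        cfg = small_config()
        world = generate_world(cfg)
        bad = pd.DataFrame(
            {
                "zip": ["Z00001"],
                "date": [dt.date(2050, 1, 1)],
                "event_id": ["E1"],
                "frac_flooded": [0.1],
                "area_flooded_sqmi": [5.0],
                "severity": ["moderate"],
                "cause": ["heavy_rain"],
            }
        )
        with pytest.raises(ConfigError, match="window"):
            generate_hospitalizations(world, bad, cfg)

    def test_full_generator_is_deterministic(self):
        cfg = small_config(n_events=5)
        out1 = fc.simulate_tables(cfg)
        out2 = fc.simulate_tables(cfg)
        pd.testing.assert_frame_equal(out1[1], out2[1])
        pd.testing.assert_frame_equal(out1[2], out2[2])
        pd.testing.assert_frame_equal(out1[3], out2[3])


def test_baseline_rates_recovered_without_effects():
    # with zero effects/covariate slopes the empirical rate per cause matches
    # the configured baseline within 3 Monte-Carlo SEs
    cfg = fc.SimConfig(
        n_zips=25,
        date_start=dt.date(2000, 1, 1),
        date_end=dt.date(2005, 12, 31),
        n_events=0,
        causes={"skin": 12.0, "injury_poisoning": 40.0},
        seasonal_amplitude=0.0,
        year_trend_slope=0.0,
        covariate_effect_sizes={},
        population_range=(1500, 1500),
        seed=17,
    )
    world = generate_world(cfg)
    counts, _ = generate_hospitalizations(world, pd.DataFrame(), cfg)
    person_days = world.population.groupby("year")["enrollees"].sum().to_dict()
    total_pd = sum(
        n * (366 if y % 4 == 0 else 365) for y, n in person_days.items()
    )
    for cause, rate in cfg.causes.items():
        total = counts.loc[counts["cause"] == cause, "count"].sum()
        expected = rate / 1e5 * total_pd
        se = np.sqrt(expected)
        assert abs(total - expected) < 3 * se


def test_synthetic_grid_writer_round_trips_through_zonal_stats():
    flood, zones = synthetic_flood_grid(n_zones=5, zone_cells=80, flood_prob=0.3, seed=2)
    out = fc.zonal_flood_fraction(flood, zones, cell_area=0.2)
    assert list(out["zone"]) == [0, 1, 2, 3, 4]
    for _, row in out.iterrows():
        mask = zones == row["zone"]
        assert row["frac_flooded"] == pytest.approx(flood[mask].mean())
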
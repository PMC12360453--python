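"""Shared fixtures: a small simulated pipeline and random model fixtures."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import floodcohort as fc
from floodcohort.simulate import random_matched_dataset as random_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated world with injected lag effects, run end to end."""
    cfg = fc.SimConfig(
        n_zips=12,
        date_start=dt.date(2000, 1, 1),
        date_end=dt.date(2006, 12, 31),
        n_events=10,
        causes={"skin": 8.0},
        lag_effects={"skin": [np.log(1.5), 0.3, 0.2, 0.1, 0.05]},
        seed=42,
    )
    world, exposures, counts, truth = fc.simulate_tables(cfg)
    flagged = fc.exposed_zip_days(exposures)
    periods = fc.filter_periods_by_cause(fc.build_exposure_periods(flagged))
    cal = fc.exposure_calendar(flagged)
    strata, attrition = fc.build_strata(
        periods, cal, fc.MatchConfig(cfg.date_start, cfg.date_end)
    )
    return {
        "config": cfg,
        "world": world,
        "exposures": exposures,
        "counts": counts,
        "truth": truth,
        "flagged": flagged,
        "periods": periods,
        "calendar": cal,
        "strata": strata,
        "attrition": attrition,
    }


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return fc.build_analytical_dataset(
        small_sim["strata"],
        small_sim["counts"],
        small_sim["world"].covariates,
        small_sim["world"].population,
        "skin",
    )




def run_pipeline(cfg: fc.SimConfig, cause: str):
    """simulate -> expose -> match -> assemble -> fit for one cause."""
    world, exposures, counts, truth = fc.simulate_tables(cfg)
    flagged = fc.exposed_zip_days(exposures)
    periods = fc.filter_periods_by_cause(fc.build_exposure_periods(flagged))
    strata, _ = fc.build_strata(
        periods,
        fc.exposure_calendar(flagged),
        fc.MatchConfig(cfg.date_start, cfg.date_end, n_lags=cfg.n_lags),
    )
    ds = fc.build_analytical_dataset(
        strata, counts, world.covariates, world.population, cause
    )
    return fc.fit_conditional_quasipoisson(ds), truth
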
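"""Self-matched control selection.

Each flood exposure period (a maximal run of consecutive exposed days in one
ZIP) is matched to two non-flooded control periods in the *same ZIP* and the
*same days of the year*, but in different years. Conditioning on these
matched strata removes time-invariant ZIP confounding and seasonality by
construction; the model later compares outcome rates between the exposed
window (and its lag weeks) and the control windows (and theirs).

Control windows must be flood-free through their full lag tail by default
(``require_clean_tail``), so that control lag weeks are not contaminated by
other floods; a config flag relaxes this to the window itself. Control years
are picked "nearest-balanced": the closest eligible year before and the
closest after the exposure year, falling back to the two nearest on one side.

Feb 29 handling: when an exposed window's day-of-year range is shifted into
a non-leap control year, Feb 29 maps to Feb 28 and the window keeps its
duration (so it ends one calendar day earlier in month-day terms).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposurePeriod

logger = logging.getLogger(__name__)


class MatchingError(ValueError):
    """Raised for corrupt matching inputs (e.g. overlapping exposure periods)."""


@dataclass
class MatchConfig:
    """Study window and control-selection policy."""

    study_start: dt.date
    study_end: dt.date
    n_lags: int = 4
    n_controls: int = 2
    policy: str = "nearest_balanced"  # or "random"
    require_clean_tail: bool = True
    censor_exposed_tail_floods: bool = False
    seed: int | None = None


@dataclass(frozen=True)
class ControlWindow:
    year: int
    start: dt.date
    end: dt.date


@dataclass(frozen=True)
class MatchedStratum:
    """One exposure period with its matched control windows."""

    stratum_id: str
    zip: str
    exposed_period: ExposurePeriod
    control_periods: tuple[ControlWindow, ...]
    n_lags: int


def _shift_to_year(d: dt.date, year: int) -> dt.date:
    """Same month-day in another year; Feb 29 maps to Feb 28 off leap years."""
    try:
        return d.replace(year=year)
    except ValueError:
        return dt.date(year, 2, 28)


def shift_window(start: dt.date, end: dt.date, year: int) -> tuple[dt.date, dt.date]:
    """Shift a window's month-day span to another year, duration preserved.

    Normally the start is anchored (same month-day, Feb 29 -> Feb 28) and the
    end is start + duration - 1. A window *ending* on Feb 29 instead anchors
    its end at Feb 28 in non-leap years, so the control also finishes on the
    last day of February (one calendar day earlier), keeping its duration by
    starting a day earlier.
    """
    dur = (end - start).days + 1
    if end.month == 2 and end.day == 29:
        new_end = _shift_to_year(end, year if end.year == start.year else year + 1)
        return new_end - dt.timedelta(days=dur - 1), new_end
    new_start = _shift_to_year(start, year)
    return new_start, new_start + dt.timedelta(days=dur - 1)


def exposure_calendar(flags: pd.DataFrame | Iterable) -> dict[str, set[dt.date]]:
    """Build a per-ZIP set of exposed dates from a flag table or period list."""
    cal: dict[str, set[dt.date]] = {}
    if isinstance(flags, pd.DataFrame):
        for z, d in zip(flags["zip"], pd.to_datetime(flags["date"]).dt.date):
            cal.setdefault(z, set()).add(d)
    else:
        for p in flags:
            cal.setdefault(p.zip, set()).update(p.days())
    return cal


def _window_clear(
    cal: Mapping[str, set[dt.date]], zip_id: str, start: dt.date, end: dt.date
) -> bool:
    days = cal.get(zip_id)
    if not days:
        return True
    d = start
    while d <= end:
        if d in days:
            return False
        d += dt.timedelta(days=1)
    return True


def candidate_controls(
    period: ExposurePeriod,
    exposure_cal: Mapping[str, set[dt.date]],
    window: tuple[dt.date, dt.date],
    n_lags: int,
    require_clean_tail: bool = True,
) -> list[ControlWindow]:
    """All candidate control windows for a period, one per eligible year.

    A year ``y`` (different from the exposure year, taken as the year of the
    period's start) is eligible when the period's month-day range shifted to
    ``y``, extended by ``n_lags`` trailing weeks, lies inside the study
    window and contains no exposed day in that ZIP.
    """
    study_start, study_end = window
    ey = period.start.year
    out: list[ControlWindow] = []
    for y in range(study_start.year, study_end.year + 1):
        if y == ey:
            continue
        start, end = shift_window(period.start, period.end, y)
        tail_end = end + dt.timedelta(days=7 * n_lags)
        if start < study_start or tail_end > study_end:
            continue
        check_end = tail_end if require_clean_tail else end
        if not _window_clear(exposure_cal, period.zip, start, check_end):
            continue
        out.append(ControlWindow(year=y, start=start, end=end))
    return out


def select_controls(
    candidates: Sequence[ControlWindow],
    exposure_year: int,
    n_controls: int = 2,
    policy: str = "nearest_balanced",
    rng: np.random.Generator | None = None,
) -> list[ControlWindow]:
    """Pick control windows from the candidates.

    ``nearest_balanced`` (default): the nearest eligible year before and the
    nearest after the exposure year; if one side is exhausted, the remaining
    picks are the nearest years on the other side. ``random`` draws uniformly
    without replacement (requires ``rng``). Returns fewer than ``n_controls``
    only when the candidate list is shorter. Output is sorted by year.
    """
    if policy == "random":
        if rng is None:
            raise MatchingError("random control selection requires an rng")
        k = min(n_controls, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        return sorted((candidates[i] for i in idx), key=lambda c: c.year)
    if policy != "nearest_balanced":
        raise MatchingError(f"unknown control selection policy {policy!r}")

    before = sorted((c for c in candidates if c.year < exposure_year), key=lambda c: exposure_year - c.year)
    after = sorted((c for c in candidates if c.year > exposure_year), key=lambda c: c.year - exposure_year)
    picks: list[ControlWindow] = []
    i = j = 0
    # alternate sides, nearest first; earlier year wins a distance tie
    while len(picks) < n_controls and (i < len(before) or j < len(after)):
        take_before = i < len(before) and (
            j >= len(after)
            or (exposure_year - before[i].year) <= (after[j].year - exposure_year)
        )
        if take_before:
            picks.append(before[i])
            i += 1
        else:
            picks.append(after[j])
            j += 1
    return sorted(picks, key=lambda c: c.year)


def build_strata(
    periods: Sequence[ExposurePeriod],
    exposure_cal: Mapping[str, set[dt.date]],
    config: MatchConfig,
) -> tuple[list[MatchedStratum], pd.DataFrame]:
    """Match every exposure period; returns (strata, attrition log).

    The attrition log has one row per input period with the outcome
    (``matched`` or a drop reason). Periods whose own lag tail leaves the
    study window are dropped (the assembled dataset would be truncated);
    periods with fewer than ``n_controls`` candidate windows are dropped.
    """
    # guard: overlapping exposure periods within a ZIP indicate corrupt input
    by_zip: dict[str, list[ExposurePeriod]] = {}
    for p in periods:
        by_zip.setdefault(p.zip, []).append(p)
    for z, ps in by_zip.items():
        ps_sorted = sorted(ps, key=lambda p: p.start)
        for a, b in zip(ps_sorted, ps_sorted[1:]):
            if b.start <= a.end:
                raise MatchingError(f"overlapping exposure periods in ZIP {z}")

    rng = np.random.default_rng(config.seed) if config.policy == "random" else None
    strata: list[MatchedStratum] = []
    log_rows = []
    for p in sorted(periods, key=lambda p: (p.zip, p.start)):
        reason = "matched"
        tail_end = p.end + dt.timedelta(days=7 * config.n_lags)
        if p.start < config.study_start or tail_end > config.study_end:
            reason = "exposed_lag_tail_outside_window"
        elif config.censor_exposed_tail_floods and not _window_clear(
            {p.zip: exposure_cal.get(p.zip, set()) - set(p.days())},
            p.zip,
            p.end + dt.timedelta(days=1),
            tail_end,
        ):
            reason = "exposed_lag_tail_contains_flood"
        else:
            cands = candidate_controls(
                p,
                exposure_cal,
                (config.study_start, config.study_end),
                config.n_lags,
                config.require_clean_tail,
            )
            controls = select_controls(
                cands, p.start.year, config.n_controls, config.policy, rng
            )
            if len(controls) < config.n_controls:
                reason = "insufficient_controls"
            else:
                strata.append(
                    MatchedStratum(
                        stratum_id=f"{p.zip}:{p.start.isoformat()}",
                        zip=p.zip,
                        exposed_period=p,
                        control_periods=tuple(controls),
                        n_lags=config.n_lags,
                    )
                )
        log_rows.append(
            {
                "zip": p.zip,
                "start": p.start.isoformat(),
                "end": p.end.isoformat(),
                "outcome": reason,
            }
        )
        if reason != "matched":
            logger.info("period %s %s dropped: %s", p.zip, p.start, reason)
    attrition = pd.DataFrame(log_rows, columns=["zip", "start", "end", "outcome"])
    return strata, attrition


def strata_to_frame(strata: Sequence[MatchedStratum]) -> pd.DataFrame:
    """Long view: one row per (stratum, arm window)."""
    rows = []
    for s in strata:
        rows.append(
            {
                "stratum_id": s.stratum_id,
                "zip": s.zip,
                "arm": "exposed",
                "window_start": s.exposed_period.start.isoformat(),
                "window_end": s.exposed_period.end.isoformat(),
                "severity": s.exposed_period.severity,
                "n_lags": s.n_lags,
            }
        )
        for k, c in enumerate(s.control_periods, start=1):
            rows.append(
                {
                    "stratum_id": s.stratum_id,
                    "zip": s.zip,
                    "arm": f"control_{k}",
                    "window_start": c.start.isoformat(),
                    "window_end": c.end.isoformat(),
                    "severity": s.exposed_period.severity,
                    "n_lags": s.n_lags,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["stratum_id", "zip", "arm", "window_start", "window_end", "severity", "n_lags"],
    )


def strata_from_frame(df: pd.DataFrame) -> list[MatchedStratum]:
    """Rebuild strata from :func:`strata_to_frame` output (CLI round trip)."""
    strata = []
    for sid, g in df.groupby("stratum_id", sort=True):
        ex = g[g["arm"] == "exposed"].iloc[0]
        period = ExposurePeriod(
            zip=str(ex["zip"]),
            start=dt.date.fromisoformat(ex["window_start"]),
            end=dt.date.fromisoformat(ex["window_end"]),
            severity=ex.get("severity", "moderate"),
        )
        controls = []
        for _, row in g[g["arm"] != "exposed"].sort_values("arm").iterrows():
            start = dt.date.fromisoformat(row["window_start"])
            controls.append(
                ControlWindow(
                    year=start.year, start=start, end=dt.date.fromisoformat(row["window_end"])
                )
            )
        strata.append(
            MatchedStratum(
                stratum_id=str(sid),
                zip=period.zip,
                exposed_period=period,
                control_periods=tuple(controls),
                n_lags=int(g["n_lags"].iloc[0]),
            )
        )
    return strata
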
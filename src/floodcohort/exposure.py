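"""Flood-exposure classification and exposure-period construction.

Turns ZIP-day flood information (a fraction/area table, or a flood-extent
grid plus a zone-id grid) into binary exposure flags and maximal runs of
consecutive exposed days ("exposure periods"), carrying severity and
flood-cause metadata.

A ZIP code and day is exposed when the mapped flood covers at least 0.5% of
the ZIP's surface area or at least 5 square miles of it; both thresholds are
configurable so that sensitivity-analysis variants can be run with the same
machinery. Boundary comparisons are inclusive ("at least").
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default exposure thresholds.
FRAC_THRESHOLD = 0.005
AREA_THRESHOLD_SQMI = 5.0

#: Ordering used when a period spans days of different severity (max wins).
SEVERITY_ORDER = {"moderate": 0, "high": 1, "extreme": 2}
SEVERITIES = ("moderate", "high", "extreme")

#: Flood causes retained by the primary analysis.
DEFAULT_ALLOWED_CAUSES = frozenset({"heavy_rain", "tropical_storm"})
FLOOD_CAUSES = ("heavy_rain", "tropical_storm", "other")


class ExposureError(ValueError):
    """Raised for invalid exposure inputs (shape mismatch, negative values...)."""


# ---------------------------------------------------------------------------
# Zonal aggregation
# ---------------------------------------------------------------------------

def zonal_flood_fraction(
    flood_grid: np.ndarray,
    zone_grid: np.ndarray,
    cell_area: float,
) -> pd.DataFrame:
    """Aggregate a binary flood-extent grid to zones (ZIP codes).

    Parameters
    ----------
    flood_grid
        Binary (0/1 or boolean) array marking flooded cells.
    zone_grid
        Integer array of the same shape assigning each cell to a zone id;
        negative ids mark cells outside any zone and are ignored.
    cell_area
        Area of one grid cell in square miles.

    Returns
    -------
    DataFrame with columns ``zone``, ``frac_flooded``, ``area_flooded_sqmi``,
    one row per zone present in ``zone_grid``.
    """
    flood = np.asarray(flood_grid)
    zones = np.asarray(zone_grid)
    if flood.shape != zones.shape:
        raise ExposureError(
            f"flood grid shape {flood.shape} != zone grid shape {zones.shape}"
        )
    if cell_area <= 0:
        raise ExposureError("cell_area must be positive")
    valid = zones >= 0
    z = zones[valid].ravel()
    f = (flood[valid].ravel() != 0).astype(np.int64)
    zone_ids, inverse = np.unique(z, return_inverse=True)
    total = np.bincount(inverse)
    flooded = np.bincount(inverse, weights=f).astype(np.int64)
    return pd.DataFrame(
        {
            "zone": zone_ids,
            "frac_flooded": flooded / total,
            "area_flooded_sqmi": cell_area * flooded,
        }
    )


def read_grid(path) -> np.ndarray:
    """Read a single-band raster (GeoTIFF or plain TIFF) into an array."""
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    return arr.squeeze()


# ---------------------------------------------------------------------------
# Exposure classification
# ---------------------------------------------------------------------------

def classify_exposure(
    frac_flooded,
    area_flooded,
    frac_threshold: float = FRAC_THRESHOLD,
    area_threshold: float = AREA_THRESHOLD_SQMI,
):
    """Binary exposure rule: flooded fraction OR flooded area meets threshold.

    Accepts scalars or arrays; comparisons are inclusive. Negative or
    non-finite inputs raise :class:`ExposureError`.
    """
    frac = np.asarray(frac_flooded, dtype=float)
    area = np.asarray(area_flooded, dtype=float)
    if not (np.all(np.isfinite(frac)) and np.all(np.isfinite(area))):
        raise ExposureError("frac_flooded/area_flooded must be finite")
    if np.any(frac < 0) or np.any(area < 0):
        raise ExposureError("frac_flooded/area_flooded must be non-negative")
    out = (frac >= frac_threshold) | (area >= area_threshold)
    if np.isscalar(frac_flooded) and np.isscalar(area_flooded):
        return bool(out)
    return out


def exposed_zip_days(
    exposures: pd.DataFrame,
    frac_threshold: float = FRAC_THRESHOLD,
    area_threshold: float = AREA_THRESHOLD_SQMI,
) -> pd.DataFrame:
    """Filter a ZIP-day flood table down to the rows meeting the exposure rule.

    ``exposures`` must have columns ``zip``, ``date``, ``frac_flooded``,
    ``area_flooded_sqmi`` and may carry ``event_id``, ``severity``, ``cause``.
    """
    flag = classify_exposure(
        exposures["frac_flooded"].to_numpy(),
        exposures["area_flooded_sqmi"].to_numpy(),
        frac_threshold,
        area_threshold,
    )
    return exposures.loc[flag].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Exposure periods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposurePeriod:
    """A maximal run of consecutive exposed days for one ZIP."""

    zip: str
    start: dt.date
    end: dt.date
    event_ids: frozenset = field(default_factory=frozenset)
    severity: str = "moderate"
    causes: frozenset = field(default_factory=lambda: frozenset({"heavy_rain"}))

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.duration_days)]


def _to_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def build_exposure_periods(zip_day_flags: pd.DataFrame) -> list[ExposurePeriod]:
    """Collapse exposed ZIP-days into maximal consecutive-day periods.

    Every row of ``zip_day_flags`` is one exposed (zip, date); a gap of one or
    more unexposed days splits periods. Severity of a multi-day period is the
    maximum over its days; causes and event ids are unions. Duplicate
    (zip, date) rows are rejected.
    """
    if len(zip_day_flags) == 0:
        return []
    df = zip_day_flags.copy()
    df["date"] = df["date"].map(_to_date)
    if df.duplicated(subset=["zip", "date"]).any():
        dup = df[df.duplicated(subset=["zip", "date"])].iloc[0]
        raise ExposureError(f"duplicate exposed day ({dup['zip']}, {dup['date']})")
    has_sev = "severity" in df.columns
    has_cause = "cause" in df.columns
    has_eid = "event_id" in df.columns

    periods: list[ExposurePeriod] = []
    for zip_id, g in df.groupby("zip", sort=True):
        g = g.sort_values("date")
        dates = g["date"].tolist()
        ords = np.array([d.toordinal() for d in dates])
        # run boundaries where consecutive dates differ by more than one day
        breaks = np.flatnonzero(np.diff(ords) > 1) + 1
        for idx in np.split(np.arange(len(dates)), breaks):
            block = g.iloc[idx]
            severity = "moderate"
            if has_sev:
                severity = max(block["severity"], key=SEVERITY_ORDER.__getitem__)
            causes = (
                frozenset(block["cause"]) if has_cause else frozenset({"heavy_rain"})
            )
            eids = frozenset(block["event_id"]) if has_eid else frozenset()
            periods.append(
                ExposurePeriod(
                    zip=zip_id,
                    start=dates[idx[0]],
                    end=dates[idx[-1]],
                    event_ids=eids,
                    severity=severity,
                    causes=causes,
                )
            )
    return periods


def filter_periods_by_cause(
    periods: Sequence[ExposurePeriod],
    allowed: Iterable[str] = DEFAULT_ALLOWED_CAUSES,
) -> list[ExposurePeriod]:
    """Keep periods whose cause set intersects ``allowed`` (rain/storm floods)."""
    allowed = frozenset(allowed)
    kept = [p for p in periods if p.causes & allowed]
    dropped = len(periods) - len(kept)
    if dropped:
        logger.info("filter_periods_by_cause: dropped %d of %d periods", dropped, len(periods))
    return kept


def periods_to_frame(periods: Sequence[ExposurePeriod]) -> pd.DataFrame:
    """Tabular view of exposure periods (one row per period)."""
    return pd.DataFrame(
        {
            "zip": [p.zip for p in periods],
            "start": [p.start.isoformat() for p in periods],
            "end": [p.end.isoformat() for p in periods],
            "duration_days": [p.duration_days for p in periods],
            "severity": [p.severity for p in periods],
            "causes": [";".join(sorted(p.causes)) for p in periods],
            "event_ids": [";".join(sorted(map(str, p.event_ids))) for p in periods],
        }
    )


def periods_from_frame(df: pd.DataFrame) -> list[ExposurePeriod]:
    """Inverse of :func:`periods_to_frame` (for the CLI round trip)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExposurePeriod(
                zip=str(row.zip),
                start=_to_date(row.start),
                end=_to_date(row.end),
                severity=row.severity,
                causes=frozenset(str(row.causes).split(";")) if row.causes else frozenset(),
                event_ids=frozenset(str(row.event_ids).split(";"))
                if getattr(row, "event_ids", "")
                else frozenset(),
            )
        )
    return out
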
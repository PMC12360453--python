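"""Analytical-dataset assembly.

Expands matched strata into the lag-structured dataset the conditional
quasi-Poisson model consumes: one row per (stratum, arm, lag window) with
the outcome count, the person-time offset, the decimal year at the window
midpoint, and window means of the meteorological/pollutant covariates; plus
the design matrix with exposure-by-lag indicators and natural-spline terms
(two degrees of freedom each) for year and every covariate mean.

Lag window l (l >= 1) is the l-th 7-day block after the arm's window; lag 0
is the window itself, whose varying length is handled purely through the
person-time offset. Person-time uses ZIP-year enrolment: the offset of a
window is the sum over its calendar days of that day's ZIP-year enrollee
count.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import MatchedStratum

COVARIATE_VARS = ("tmax", "rhmax", "wind", "pm25", "no2", "o3")
ARMS = ("exposed", "control_1", "control_2")


class AssemblyError(ValueError):
    """Raised for inconsistent assembly inputs (coverage gaps, negatives...)."""


# ---------------------------------------------------------------------------
# Lag windows
# ---------------------------------------------------------------------------

def lag_windows(stratum: MatchedStratum) -> list[tuple[str, int, dt.date, dt.date]]:
    """All (arm, lag, start, end) windows of a stratum.

    For each arm, lag 0 is the arm's own window; lag l covers days
    ``end + 7(l-1) + 1`` through ``end + 7l``.
    """
    windows = []
    arm_spans = [("exposed", stratum.exposed_period.start, stratum.exposed_period.end)]
    for k, c in enumerate(stratum.control_periods, start=1):
        arm_spans.append((f"control_{k}", c.start, c.end))
    for arm, start, end in arm_spans:
        windows.append((arm, 0, start, end))
        for l in range(1, stratum.n_lags + 1):
            ws = end + dt.timedelta(days=7 * (l - 1) + 1)
            we = end + dt.timedelta(days=7 * l)
            windows.append((arm, l, ws, we))
    return windows


# ---------------------------------------------------------------------------
# Window aggregation primitives
# ---------------------------------------------------------------------------

def aggregate_counts(
    counts: pd.DataFrame,
    zip_id: str,
    window: tuple[dt.date, dt.date],
    cause: str,
    admission_filter: str | None = None,
) -> int:
    """Sum hospitalisation counts for a ZIP/cause over a date window.

    Missing (zip, date) rows count as zero; negative counts are rejected.
    ``admission_filter`` restricts to one admission type when the table
    carries an ``admission_type`` column.
    """
    if len(counts) == 0:
        return 0
    if (counts["count"] < 0).any():
        raise AssemblyError("negative counts in input")
    sel = (counts["zip"] == zip_id) & (counts["cause"] == cause)
    if admission_filter is not None:
        sel &= counts["admission_type"] == admission_filter
    sub = counts.loc[sel]
    if len(sub) == 0:
        return 0
    d = pd.to_datetime(sub["date"]).dt.date
    start, end = window
    return int(sub.loc[(d >= start) & (d <= end), "count"].sum())


def person_time_offset(
    population: Mapping[tuple[str, int], int] | pd.DataFrame,
    zip_id: str,
    window: tuple[dt.date, dt.date],
) -> float:
    """Person-days in a window: Σ over days of the ZIP-year enrollee count."""
    if isinstance(population, pd.DataFrame):
        population = {
            (z, int(y)): int(n)
            for z, y, n in zip(population["zip"], population["year"], population["enrollees"])
        }
    start, end = window
    total = 0.0
    for y in range(start.year, end.year + 1):
        seg_start = max(start, dt.date(y, 1, 1))
        seg_end = min(end, dt.date(y, 12, 31))
        n_days = (seg_end - seg_start).days + 1
        key = (zip_id, y)
        if key not in population:
            raise AssemblyError(f"missing population for ZIP {zip_id}, year {y}")
        enrollees = population[key]
        if enrollees <= 0:
            raise AssemblyError(f"non-positive enrolment for ZIP {zip_id}, year {y}")
        total += n_days * enrollees
    return total


def aggregate_covariates(
    covariates: pd.DataFrame,
    zip_id: str,
    window: tuple[dt.date, dt.date],
    variables: Sequence[str] = COVARIATE_VARS,
    missing_tolerance: int = 0,
) -> dict[str, float]:
    """Arithmetic means of covariates over a window's days.

    Up to ``missing_tolerance`` absent days are allowed (mean over present
    days); beyond that the window is rejected.
    """
    start, end = window
    sub = covariates[covariates["zip"] == zip_id]
    d = pd.to_datetime(sub["date"]).dt.date
    sub = sub.loc[(d >= start) & (d <= end)]
    n_expected = (end - start).days + 1
    missing = n_expected - len(sub)
    if missing > missing_tolerance:
        raise AssemblyError(
            f"{missing} covariate days missing for ZIP {zip_id} in [{start}, {end}]"
        )
    return {v: float(sub[v].mean()) for v in variables}


def year_fraction(d: dt.date) -> float:
    """Decimal year at the middle of calendar day ``d``."""
    year_len = 366 if dt.date(d.year, 12, 31).timetuple().tm_yday == 366 else 365
    return d.year + (d.timetuple().tm_yday - 0.5) / year_len


# ---------------------------------------------------------------------------
# Natural cubic splines
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Natural cubic spline basis with frozen knots.

    ``df`` columns; boundary knots at the training min/max, ``df - 1``
    interior knots at equally spaced quantiles (df=2: the median). The basis
    is linear beyond the boundary knots (zero second derivative), and new
    points are evaluated against the stored knots.
    """

    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    basis: np.ndarray = field(repr=False)

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        knots = np.concatenate(
            ([self.boundary_knots[0]], self.interior_knots, [self.boundary_knots[1]])
        )
        return _ns_design(x, knots)


def _ns_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline basis (no intercept).

    With K knots the basis has K-1 columns: x itself and, for k = 1..K-2,
    d_k(x) - d_{K-1}(x) with d_k(x) = [(x-k_k)^3_+ - (x-k_K)^3_+]/(k_K - k_k).
    The cubic and quadratic terms cancel beyond the last knot, leaving a
    function linear outside the boundary knots.
    """
    K = len(knots)

    def d(k_idx: int) -> np.ndarray:
        num = np.clip(x - knots[k_idx], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k_idx])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def natural_spline_basis(x, df: int = 2) -> SplineBasis:
    """Fit a natural cubic spline basis to ``x`` (df columns, frozen knots)."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) < df + 1:
        raise AssemblyError(
            f"natural spline with df={df} needs at least {df + 1} distinct values, got {len(uniq)}"
        )
    boundary = (float(uniq[0]), float(uniq[-1]))
    qs = [k / df for k in range(1, df)]
    interior = np.quantile(x, qs)
    basis = SplineBasis(
        df=df, interior_knots=np.atleast_1d(interior), boundary_knots=boundary, basis=None
    )
    basis.basis = basis.transform(x)
    return basis


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class AnalyticalDataset:
    """Rows + design matrix for one cause's conditional model."""

    rows: pd.DataFrame
    X: np.ndarray
    y: np.ndarray
    log_offset: np.ndarray
    stratum_index: np.ndarray  # integer stratum codes, aligned with rows
    stratum_ids: list[str]
    columns: list[str]
    spline_bases: dict[str, SplineBasis]
    cause: str
    n_lags: int

    @property
    def n_exposure_terms(self) -> int:
        return self.n_lags + 1

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.rows.to_csv(path, index=False)
        if sidecar:
            meta = {
                "cause": self.cause,
                "n_lags": self.n_lags,
                "columns": self.columns,
                "splines": {
                    name: {
                        "df": b.df,
                        "interior_knots": list(map(float, b.interior_knots)),
                        "boundary_knots": list(b.boundary_knots),
                    }
                    for name, b in self.spline_bases.items()
                },
            }
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


class _DailySeries:
    """Per-ZIP daily arrays with prefix sums for O(1) window aggregation."""

    def __init__(self, start: dt.date, end: dt.date):
        self.start = start
        self.n_days = (end - start).days + 1

    def idx(self, d: dt.date) -> int:
        i = (d - self.start).days
        if i < 0 or i >= self.n_days:
            raise AssemblyError(f"date {d} outside assembled coverage")
        return i


def build_analytical_dataset(
    strata: Sequence[MatchedStratum],
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    population: pd.DataFrame | Mapping[tuple[str, int], int],
    cause: str,
    admission_filter: str | None = None,
    cov_vars: Sequence[str] = COVARIATE_VARS,
    spline_df: int = 2,
    missing_tolerance: int = 0,
) -> AnalyticalDataset:
    """Expand strata into rows and build the model design matrix.

    Rows: all strata x 3 arms x (n_lags+1) lags. Design matrix columns, in
    order: the exposure-by-lag indicators ``lag0..lagL`` (1 iff arm=exposed
    at that lag), two natural-spline columns for decimal year, then two per
    covariate mean. Splines are fit on the assembled rows of this dataset
    (one model fit per cause). The log person-time offset is returned
    separately.
    """
    if not strata:
        raise AssemblyError("no strata to assemble")
    n_lags = strata[0].n_lags
    if any(s.n_lags != n_lags for s in strata):
        raise AssemblyError("strata have inconsistent n_lags")
    if (counts["count"] < 0).any():
        raise AssemblyError("negative counts in input")

    # ---- fast daily lookup structures -------------------------------------
    cov_dates = pd.to_datetime(covariates["date"])
    span = _DailySeries(cov_dates.min().date(), cov_dates.max().date())
    zips_needed = sorted({s.zip for s in strata})
    zmap = {z: i for i, z in enumerate(zips_needed)}
    nz, nd = len(zips_needed), span.n_days

    # counts -> (zip, day) matrix for this cause (+ admission filter)
    sel = counts["cause"] == cause
    if admission_filter is not None:
        if "admission_type" not in counts.columns:
            raise AssemblyError("admission_filter given but counts lack admission_type")
        sel &= counts["admission_type"] == admission_filter
    sub = counts.loc[sel & counts["zip"].isin(zips_needed)]
    cmat = np.zeros((nz, nd), dtype=np.int64)
    if len(sub):
        zi = sub["zip"].map(zmap).to_numpy()
        di = (pd.to_datetime(sub["date"]) - pd.Timestamp(span.start)).dt.days.to_numpy()
        if (di < 0).any() or (di >= nd).any():
            raise AssemblyError("count dates outside covariate coverage")
        np.add.at(cmat, (zi, di), sub["count"].to_numpy())
    ccum = np.concatenate([np.zeros((nz, 1)), np.cumsum(cmat, axis=1)], axis=1)

    # covariates -> (zip, day) matrices + presence mask
    covsub = covariates[covariates["zip"].isin(zips_needed)]
    czi = covsub["zip"].map(zmap).to_numpy()
    cdi = (pd.to_datetime(covsub["date"]) - pd.Timestamp(span.start)).dt.days.to_numpy()
    present = np.zeros((nz, nd), dtype=np.int64)
    present[czi, cdi] = 1
    pcum = np.concatenate([np.zeros((nz, 1)), np.cumsum(present, axis=1)], axis=1)
    vcum = {}
    for v in cov_vars:
        m = np.zeros((nz, nd))
        m[czi, cdi] = covsub[v].to_numpy()
        vcum[v] = np.concatenate([np.zeros((nz, 1)), np.cumsum(m, axis=1)], axis=1)

    # population -> (zip, day) daily enrolment
    if isinstance(population, pd.DataFrame):
        pop_lookup = {
            (z, int(y)): int(n)
            for z, y, n in zip(population["zip"], population["year"], population["enrollees"])
        }
    else:
        pop_lookup = dict(population)
    years_span = range(span.start.year, (span.start + dt.timedelta(days=nd - 1)).year + 1)
    day_year = np.array(
        [(span.start + dt.timedelta(days=i)).year for i in range(nd)]
    )
    pmat = np.zeros((nz, nd))
    for z, zix in zmap.items():
        for y in years_span:
            key = (z, y)
            if key in pop_lookup:
                if pop_lookup[key] <= 0:
                    raise AssemblyError(f"non-positive enrolment for ZIP {z}, year {y}")
                pmat[zix, day_year == y] = pop_lookup[key]
    popcum = np.concatenate([np.zeros((nz, 1)), np.cumsum(pmat, axis=1)], axis=1)

    def wsum(cum: np.ndarray, zi: int, a: int, b: int) -> float:
        return float(cum[zi, b + 1] - cum[zi, a])

    # ---- expand rows -------------------------------------------------------
    recs = []
    for s_idx, s in enumerate(strata):
        zi = zmap[s.zip]
        for arm, lag, ws, we in lag_windows(s):
            a, b = span.idx(ws), span.idx(we)
            n_days_w = b - a + 1
            n_present = int(wsum(pcum, zi, a, b))
            if n_days_w - n_present > missing_tolerance:
                raise AssemblyError(
                    f"{n_days_w - n_present} covariate days missing for ZIP {s.zip} "
                    f"in [{ws}, {we}]"
                )
            if n_present == 0:
                raise AssemblyError(f"no covariate coverage for ZIP {s.zip} in [{ws}, {we}]")
            person_days = wsum(popcum, zi, a, b)
            if person_days <= 0 or np.any(pmat[zi, a : b + 1] <= 0):
                raise AssemblyError(
                    f"missing/zero enrolment for ZIP {s.zip} in [{ws}, {we}]"
                )
            mid = ws + dt.timedelta(days=(we - ws).days // 2)
            rec = {
                "stratum_id": s.stratum_id,
                "zip": s.zip,
                "arm": arm,
                "lag": lag,
                "cause": cause,
                "count": int(wsum(ccum, zi, a, b)),
                "person_days": person_days,
                "year_frac": year_fraction(mid),
            }
            for v in cov_vars:
                rec[v] = wsum(vcum[v], zi, a, b) / n_present
            recs.append((s_idx, rec))

    rows = pd.DataFrame([r for _, r in recs])
    stratum_codes = np.array([i for i, _ in recs], dtype=np.int64)

    # ---- design matrix -----------------------------------------------------
    exposed = (rows["arm"] == "exposed").to_numpy()
    X_cols = []
    columns = []
    for l in range(n_lags + 1):
        X_cols.append((exposed & (rows["lag"].to_numpy() == l)).astype(float))
        columns.append(f"lag{l}")
    spline_bases: dict[str, SplineBasis] = {}
    for name, values in [("year", rows["year_frac"].to_numpy())] + [
        (v, rows[v].to_numpy()) for v in cov_vars
    ]:
        basis = natural_spline_basis(values, df=spline_df)
        spline_bases[name] = basis
        for j in range(basis.basis.shape[1]):
            X_cols.append(basis.basis[:, j])
            columns.append(f"{name}_ns{j + 1}")
    X = np.column_stack(X_cols)

    return AnalyticalDataset(
        rows=rows,
        X=X,
        y=rows["count"].to_numpy(dtype=float),
        log_offset=np.log(rows["person_days"].to_numpy(dtype=float)),
        stratum_index=stratum_codes,
        stratum_ids=[s.stratum_id for s in strata],
        columns=columns,
        spline_bases=spline_bases,
        cause=cause,
        n_lags=n_lags,
    )


def filter_subcauses(
    counts: pd.DataFrame,
    mapping: pd.DataFrame,
    min_total: int = 20_000,
) -> list[str]:
    """Subcause labels meeting the inclusion rule (>= ``min_total`` admissions).

    ``mapping`` is a two-column table (``code`` -> ``cause``) applied verbatim
    to a line-level or coded count table with a ``code`` column; when
    ``counts`` already carries ``cause`` labels the mapping is optional.
    """
    df = counts
    if "code" in df.columns and mapping is not None:
        df = df.merge(mapping, on="code", how="inner")
    totals = df.groupby("cause")["count"].sum()
    return sorted(totals.index[totals >= min_total])
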
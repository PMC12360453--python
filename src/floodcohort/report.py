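"""Descriptive reporting utilities.

Small helpers for the study-census style summaries: percentage shares of
event severities and flood causes, cause-of-hospitalisation shares, and a
forest-plot-layout table of effect estimates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .exposure import ExposurePeriod


def percentage_share(part: float, whole: float, decimals: int = 0) -> float:
    """100 * part / whole, rounded to the printed precision."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals) if decimals > 0 else round(
        100.0 * part / whole
    )


def percentage_shares(counts: Mapping[str, float], decimals: int = 0) -> dict[str, float]:
    """Percentage share of each category in a count table."""
    total = float(sum(counts.values()))
    return {k: percentage_share(v, total, decimals) for k, v in counts.items()}


def event_census(exposures: pd.DataFrame) -> dict:
    """Summary of the flood-event census from a ZIP-day exposure table.

    Counts distinct events, their duration range, and severity / flood-cause
    shares (as whole percentages, one severity/cause per event).
    """
    ev = exposures.groupby("event_id").agg(
        severity=("severity", "first"),
        cause=("cause", "first"),
        start=("date", "min"),
        end=("date", "max"),
    )
    durations = (pd.to_datetime(ev["end"]) - pd.to_datetime(ev["start"])).dt.days + 1
    return {
        "n_events": int(len(ev)),
        "duration_min_days": int(durations.min()),
        "duration_max_days": int(durations.max()),
        "severity_counts": ev["severity"].value_counts().to_dict(),
        "severity_shares_pct": percentage_shares(ev["severity"].value_counts().to_dict()),
        "cause_counts": ev["cause"].value_counts().to_dict(),
        "cause_shares_pct": percentage_shares(ev["cause"].value_counts().to_dict()),
    }


def hospitalization_shares(counts: pd.DataFrame, decimals: int = 1) -> dict[str, float]:
    """Share of total hospitalisations by cause (percent, one decimal)."""
    totals = counts.groupby("cause")["count"].sum().to_dict()
    return percentage_shares(totals, decimals)


def forest_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot-layout table: causes x (lag 0..L, mean), estimate and CI."""
    df = effects.copy()
    df["estimate"] = [
        f"{p:+.1f}% ({lo:.1f} to {hi:.1f})"
        for p, lo, hi in zip(df["pct_change"], df["ci_low"], df["ci_high"])
    ]
    cols = [c for c in ("stratifier", "stratum") if c in df.columns]
    return df.pivot_table(
        index=cols + ["cause"], columns="lag", values="estimate", aggfunc="first"
    ).reset_index()


def match_rate(attrition: pd.DataFrame) -> dict:
    """Attrition summary: periods in, strata matched, drop reasons."""
    outcome = attrition["outcome"].value_counts().to_dict()
    n = int(len(attrition))
    matched = int(outcome.get("matched", 0))
    return {
        "n_periods": n,
        "n_matched": matched,
        "match_rate": matched / n if n else float("nan"),
        "drop_reasons": {k: int(v) for k, v in outcome.items() if k != "matched"},
    }
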
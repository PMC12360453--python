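"""Stratified and secondary analyses.

Drives the model over subgroups of the matched strata: flood severity
(moderate vs high-or-extreme), season of the exposed period's start (warm =
April-September by default), admission type (emergency vs non-emergency,
which re-aggregates counts rather than splitting strata), and ZIP-level
census splits (% Black residents, median household income, poverty rate)
at the median over exposed ZIPs.

Stratum-level and ZIP-level stratifiers partition whole matched strata —
a stratum is never split across analyses — while the admission-type
stratifier re-fits the same strata on filtered counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assemble import build_analytical_dataset
from .matching import MatchedStratum
from .model import effects_table, fit_conditional_quasipoisson, lag_effects, mean_effect

logger = logging.getLogger(__name__)

WARM_MONTHS = frozenset(range(4, 10))  # April..September


class StratifyError(ValueError):
    """Raised for unresolvable stratifier specifications."""


@dataclass
class Stratifier:
    """A declarative split of the analysis into subgroups.

    ``kind`` is one of ``stratum_level`` (severity, season: partitions
    matched strata by their own metadata), ``zip_level`` (partitions strata
    by a ZIP census split), or ``row_level`` (admission type: same strata,
    filtered counts).
    """

    name: str
    kind: str
    rule: Callable[[MatchedStratum], str] | Mapping[str, str] | Sequence[str]


def median_split(
    zip_values: Mapping[str, float] | pd.Series,
    threshold: float | None = None,
) -> dict[str, str]:
    """Label ZIPs ``higher``/``lower`` by a median (or explicit) threshold.

    ZIPs strictly above the threshold are ``higher``. With no explicit
    threshold the median of the supplied values is used; all-identical
    values are rejected (no split exists).
    """
    s = pd.Series(zip_values, dtype=float)
    if len(s) < 2 or s.nunique() < 2:
        raise StratifyError("median_split needs at least two distinct values")
    thr = float(s.median()) if threshold is None else float(threshold)
    labels = {z: ("higher" if v > thr else "lower") for z, v in s.items()}
    logger.info("median_split threshold = %.6g", thr)
    return labels


def severity_stratifier() -> Stratifier:
    """Moderate vs high-or-extreme, from the exposed period's severity."""
    return Stratifier(
        name="severity",
        kind="stratum_level",
        rule=lambda s: (
            "moderate" if s.exposed_period.severity == "moderate" else "high_or_extreme"
        ),
    )


def season_stratifier(warm_months: frozenset[int] = WARM_MONTHS) -> Stratifier:
    """Warm vs cold season by the exposed period's start month."""
    return Stratifier(
        name="season",
        kind="stratum_level",
        rule=lambda s: "warm" if s.exposed_period.start.month in warm_months else "cold",
    )


def admission_stratifier() -> Stratifier:
    """Emergency vs non-emergency admissions (count re-aggregation)."""
    return Stratifier(
        name="admission_type", kind="row_level", rule=("emergency", "non_emergency")
    )


def zip_level_stratifier(
    name: str,
    census: pd.DataFrame,
    exposed_zips: Sequence[str],
    threshold: float | None = None,
) -> Stratifier:
    """Higher/lower split of a census column over the exposed ZIPs."""
    if name not in census.columns:
        raise StratifyError(f"census table lacks column {name!r}")
    vals = census.set_index("zip").loc[
        [z for z in census["zip"] if z in set(exposed_zips)], name
    ]
    labels = median_split(vals, threshold)
    return Stratifier(name=name, kind="zip_level", rule=labels)


def stratify_strata(
    strata: Sequence[MatchedStratum],
    stratifier: Stratifier,
) -> dict[str, list[MatchedStratum]]:
    """Partition matched strata into stratifier categories (whole strata).

    Only meaningful for ``stratum_level`` / ``zip_level`` stratifiers; the
    union of outputs is the input.
    """
    groups: dict[str, list[MatchedStratum]] = {}
    if stratifier.kind == "stratum_level":
        for s in strata:
            groups.setdefault(stratifier.rule(s), []).append(s)
    elif stratifier.kind == "zip_level":
        labels = stratifier.rule
        for s in strata:
            if s.zip not in labels:
                raise StratifyError(
                    f"ZIP {s.zip} unresolvable under stratifier {stratifier.name!r}"
                )
            groups.setdefault(labels[s.zip], []).append(s)
    else:
        raise StratifyError(
            f"stratifier kind {stratifier.kind!r} does not partition strata"
        )
    return groups


def run_stratified(
    strata: Sequence[MatchedStratum],
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    population: pd.DataFrame,
    cause: str,
    stratifier: Stratifier,
    alpha: float = 0.05,
    m: int | None = None,
    dispersion_floor: float | None = None,
) -> pd.DataFrame:
    """Fit the model within each stratifier category; tidy effect table.

    Returns columns (stratifier, stratum, cause, lag, pct_change, ci_low,
    ci_high, alpha, m_comparisons). Categories without strata are skipped
    with a warning.
    """
    if stratifier.kind == "row_level":
        jobs = {level: (list(strata), level) for level in stratifier.rule}
    else:
        jobs = {
            label: (group, None)
            for label, group in stratify_strata(strata, stratifier).items()
        }

    tables = []
    for label in sorted(jobs):
        group, admission = jobs[label]
        if not group:
            logger.warning("stratum %s=%s has no matched strata; skipped", stratifier.name, label)
            continue
        ds = build_analytical_dataset(
            group, counts, covariates, population, cause, admission_filter=admission
        )
        fit = fit_conditional_quasipoisson(ds, dispersion_floor=dispersion_floor)
        effects = lag_effects(fit, alpha=alpha, m=m) + [
            mean_effect(fit, alpha=alpha, m=m)
        ]
        tab = effects_table(effects)
        tab.insert(0, "stratum", label)
        tab.insert(0, "stratifier", stratifier.name)
        tables.append(tab)
    if not tables:
        raise StratifyError("no stratum produced a fit")
    return pd.concat(tables, ignore_index=True)
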
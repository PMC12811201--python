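"""Outcome layer: prevented events, resource use, and efficiency metrics.

Prevented cases and deaths are differences in cumulative 10-year clinical
CRC cases / CRC deaths between an intervention arm and its matched
no-screening arm (same age, sex, cohort size, horizon, parameter set).
Efficiency is expressed as resources per prevented event (colonoscopies or
FIT kits per prevented case or death); when an arm prevents nothing (or a
negative number of events) the ratio is undefined and reported as NaN
rather than raising.  Negative prevented counts are retained as-is so that
"prevented X% fewer" comparisons remain expressible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ComparisonError, MissingReferenceError
from .natural_history import CohortTrajectory

#: Metrics emitted into league tables, in fixed row order.
LEAGUE_METRICS = (
    "crc_cases_10y",
    "crc_deaths_10y",
    "prevented_cases",
    "prevented_deaths",
    "colonoscopies_total",
    "fits_total",
    "colonoscopies_per_prevented_case",
    "colonoscopies_per_prevented_death",
    "fits_per_prevented_case",
    "fits_per_prevented_death",
)


@dataclass(frozen=True)
class OutcomeSummary:
    """Cumulative outcomes of one arm, with prevented-event and efficiency
    metrics relative to its matched no-screening arm."""

    strategy_label: str
    cutoff: Optional[float]
    age: int
    sex: str
    n: int
    crc_cases_10y: float
    crc_deaths_10y: float
    colonoscopies_total: float
    fits_total: float
    prevented_cases: float
    prevented_deaths: float
    colonoscopies_per_prevented_case: float = float("nan")
    colonoscopies_per_prevented_death: float = float("nan")
    fits_per_prevented_case: float = float("nan")
    fits_per_prevented_death: float = float("nan")


def _check_comparable(intervention: CohortTrajectory, reference: CohortTrajectory) -> None:
    a, b = intervention.meta, reference.meta
    mismatches = [
        name
        for name in ("age", "sex", "n", "horizon")
        if getattr(a, name) != getattr(b, name)
    ]
    if mismatches:
        raise ComparisonError(
            f"arms are not comparable; mismatched fields: {mismatches}"
        )


def prevented_events(
    intervention: CohortTrajectory, reference: CohortTrajectory
) -> tuple[float, float]:
    """(prevented cases, prevented deaths) = reference − intervention.

    Values may be negative and are reported as-is.
    """
    _check_comparable(intervention, reference)
    return (
        reference.cases_total - intervention.cases_total,
        reference.deaths_total - intervention.deaths_total,
    )


def efficiency_ratios(summary: OutcomeSummary) -> dict[str, float]:
    """Resources per prevented event; NaN when prevented events ≤ 0."""

    def _ratio(resource: float, prevented: float) -> float:
        return resource / prevented if prevented > 0 else float("nan")

    return {
        "colonoscopies_per_prevented_case": _ratio(
            summary.colonoscopies_total, summary.prevented_cases
        ),
        "colonoscopies_per_prevented_death": _ratio(
            summary.colonoscopies_total, summary.prevented_deaths
        ),
        "fits_per_prevented_case": _ratio(summary.fits_total, summary.prevented_cases),
        "fits_per_prevented_death": _ratio(
            summary.fits_total, summary.prevented_deaths
        ),
    }


def summarize_arm(
    intervention: CohortTrajectory,
    reference: CohortTrajectory,
    cutoff: Optional[float] = None,
) -> OutcomeSummary:
    """Build the full outcome summary of one arm against its reference."""
    pc, pdth = prevented_events(intervention, reference)
    meta = intervention.meta
    base = OutcomeSummary(
        strategy_label=meta.strategy_label,
        cutoff=cutoff,
        age=meta.age,
        sex=meta.sex,
        n=meta.n,
        crc_cases_10y=intervention.cases_total,
        crc_deaths_10y=intervention.deaths_total,
        colonoscopies_total=intervention.colonoscopies_total,
        fits_total=intervention.fits_total,
        prevented_cases=pc,
        prevented_deaths=pdth,
    )
    return replace(base, **efficiency_ratios(base))


def pool_sexes(summaries: Iterable[OutcomeSummary]) -> list[OutcomeSummary]:
    """Pool per-sex summaries of the same arm (counts summed, cohort sizes
    summed, ratios recomputed); pooled rows carry ``sex='pooled'``."""
    by_key: dict[tuple, list[OutcomeSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.strategy_label, s.cutoff, s.age), []).append(s)
    pooled = []
    for (label, cutoff, age), group in by_key.items():
        base = OutcomeSummary(
            strategy_label=label,
            cutoff=cutoff,
            age=age,
            sex="pooled",
            n=sum(s.n for s in group),
            crc_cases_10y=sum(s.crc_cases_10y for s in group),
            crc_deaths_10y=sum(s.crc_deaths_10y for s in group),
            colonoscopies_total=sum(s.colonoscopies_total for s in group),
            fits_total=sum(s.fits_total for s in group),
            prevented_cases=sum(s.prevented_cases for s in group),
            prevented_deaths=sum(s.prevented_deaths for s in group),
        )
        pooled.append(replace(base, **efficiency_ratios(base)))
    return pooled


def relative_difference(metric_a: float, metric_b: float) -> float:
    """Percent difference of a vs. baseline b: 100·(a−b)/b.

    Undefined (NaN) for a non-positive baseline.
    """
    if metric_b is None or not metric_b > 0:
        return float("nan")
    return 100.0 * (metric_a - metric_b) / metric_b


def league_table(
    summaries: Sequence[OutcomeSummary],
    reference_labels: Sequence[str] = ("colonoscopy_q10y", "biennial_fit"),
) -> pd.DataFrame:
    """Long-format comparison table across a grid of arms.

    One row per (arm, metric) with the metric value and, for each reference
    strategy present in the same (age, sex) cell, the relative difference in
    percent (rounded to integer percent; NaN where undefined).  Raises when
    none of the requested reference strategies is present anywhere.
    """
    summaries = list(summaries)
    if not summaries:
        raise MissingReferenceError("empty summary grid")
    labels_present = {s.strategy_label for s in summaries}
    active_refs = [ref for ref in reference_labels if ref in labels_present]
    if reference_labels and not active_refs:
        raise MissingReferenceError(
            f"no reference arm among {tuple(reference_labels)} present in the grid "
            f"(arms: {sorted(labels_present)})"
        )

    ref_values: dict[tuple, OutcomeSummary] = {}
    for s in summaries:
        if s.strategy_label in active_refs:
            ref_values[(s.strategy_label, s.age, s.sex)] = s

    strategy_order = {s.strategy_label: i for i, s in enumerate(summaries)}
    rows = []
    for s in summaries:
        for metric in LEAGUE_METRICS:
            value = getattr(s, metric)
            row = {
                "strategy": s.strategy_label,
                "cutoff": s.cutoff,
                "age": s.age,
                "sex": s.sex,
                "metric": metric,
                "value": value,
            }
            for ref in active_refs:
                ref_summary = ref_values.get((ref, s.age, s.sex))
                if ref_summary is None:
                    rel = float("nan")
                else:
                    rel = relative_difference(value, getattr(ref_summary, metric))
                row[f"rel_vs_{ref}_pct"] = (
                    float(np.round(rel)) if math.isfinite(rel) else float("nan")
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    metric_order = {m: i for i, m in enumerate(LEAGUE_METRICS)}
    df = df.sort_values(
        by=["age", "sex", "strategy", "metric"],
        key=lambda col: (
            col.map(metric_order)
            if col.name == "metric"
            else col.map(strategy_order)
            if col.name == "strategy"
            else col
        ),
        kind="stable",
    ).reset_index(drop=True)
    return df


def pivot_export(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Figure-style pivot of one metric: strategies as rows, age × sex as
    columns — the layout used for panelled comparisons by age."""
    sub = table[table["metric"] == metric]
    return sub.pivot_table(
        index="strategy", columns=["age", "sex"], values="value", dropna=False
    )
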
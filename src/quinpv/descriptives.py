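"""Descriptive tabulations of a line listing.

Case-series style summaries: demographics and categorical distributions
(gender, seriousness, outcome, reporter, causality, suspected drug and
generation, suspect-drug multiplicity), preferred-term frequency tables
per SOC, SOC shares of all reported ADRs, the ADRs-per-report ratio, and
five-number summaries of time to onset per SOC group.

Display conventions: percentages rounded half-away-from-zero at one
decimal; quartiles by linear interpolation between order statistics;
missing categorical values form an explicit "not_available" level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cases import icsr_time_to_event, naranjo_score
from .disproportionality import round_half_away
from .icsr import (
    ICSR,
    CountTable,
    SocCategory,
    SocGroup,
    TARGET_SOCS,
    classify_icsr_soc_group,
    normalize_term,
)

__all__ = [
    "SummaryTable",
    "summarize_cases",
    "pt_frequency",
    "soc_share",
    "adrs_per_icsr",
    "tte_distribution",
    "age_group",
    "AGE_GROUP_LABELS",
]

#: National-style age grouping.  The published labels "18-65" / "> 66"
#: leave 65-66 ambiguous; the gap is closed at 66 (ages in [65, 66) fall in
#: the adult bin) while the display labels are kept.
AGE_GROUP_LABELS = ("<1 month", "1-23 months", "2-11 years", "12-17 years",
                    "18-65 years", ">66 years")
_AGE_EDGES_YEARS = (1 / 12, 2.0, 12.0, 18.0, 66.0)


def age_group(age_years: float) -> str:
    for edge, label in zip(_AGE_EDGES_YEARS, AGE_GROUP_LABELS):
        if age_years < edge:
            return label
    return AGE_GROUP_LABELS[-1]


@dataclass
class SummaryTable:
    """Named blocks of (level, count, percent) plus continuous summaries."""

    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)
    age: Optional[dict[str, float]] = None  # median, q1, q3, n

    def block(self, name: str) -> pd.DataFrame:
        return self.blocks[name]


def _categorical_block(values: Sequence[str]) -> pd.DataFrame:
    counts = pd.Series(values).value_counts()
    n = int(counts.sum())
    return pd.DataFrame(
        {
            "level": counts.index,
            "count": counts.values,
            "percent": [round_half_away(100.0 * c / n, 1) for c in counts.values],
        }
    )


def summarize_cases(icsrs: Sequence[ICSR]) -> SummaryTable:
    """Case-series summary (the shape of a demographics table).

    Blocks: gender, age_group, seriousness, outcome, reporter, causality,
    drug, generation, suspect_multiplicity; continuous: age median / IQR
    over non-missing ages (linear-interpolation quartiles).
    """
    table = SummaryTable()
    if not icsrs:
        return table

    table.blocks["gender"] = _categorical_block([r.gender.value for r in icsrs])
    table.blocks["seriousness"] = _categorical_block([r.seriousness.value for r in icsrs])
    table.blocks["outcome"] = _categorical_block([r.outcome.value for r in icsrs])
    table.blocks["reporter"] = _categorical_block(
        [r.reporter.value if r.reporter else "not_available" for r in icsrs]
    )
    table.blocks["causality"] = _categorical_block(
        [
            naranjo_score(r.naranjo_answers).category.value
            if r.naranjo_answers is not None
            else "not_available"
            for r in icsrs
        ]
    )
    table.blocks["suspect_multiplicity"] = _categorical_block(
        [">1" if r.n_suspect_drugs_total > 1 else "1" for r in icsrs]
    )

    drug_rows, gen_rows = [], []
    for r in icsrs:
        seen_drugs, seen_gens = set(), set()
        for s in r.suspects:
            if s.drug.name not in seen_drugs:
                drug_rows.append(s.drug.name)
                seen_drugs.add(s.drug.name)
            if s.drug.generation not in seen_gens:
                gen_rows.append(f"gen{s.drug.generation}")
                seen_gens.add(s.drug.generation)
    table.blocks["drug"] = _categorical_block(drug_rows)
    table.blocks["generation"] = _categorical_block(gen_rows)

    ages = [r.age_years for r in icsrs if r.age_years is not None]
    if ages:
        q1, med, q3 = np.percentile(ages, [25, 50, 75])  # linear interpolation
        table.age = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(ages)}
        table.blocks["age_group"] = _categorical_block([age_group(a) for a in ages])
    return table


def pt_frequency(icsrs: Iterable[ICSR], soc: SocCategory) -> pd.DataFrame:
    """Ranked preferred-term frequency for one target SOC.

    Counts are over adverse events (each event once); the percentage
    denominator is the SOC event total.  Ties rank alphabetically.
    """
    if soc not in TARGET_SOCS:
        raise ValueError(f"{soc} is not a target SOC")
    counts: dict[str, int] = {}
    for icsr in icsrs:
        for event in icsr.events:
            if event.soc is soc:
                key = normalize_term(event.preferred_term)
                counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "preferred_term": [pt for pt, _ in ordered],
            "count": [c for _, c in ordered],
            "percent": [round_half_away(100.0 * c / total, 1) for _, c in ordered],
        }
    )


def soc_share(counts: CountTable) -> pd.DataFrame:
    """Per-SOC totals and percentage of all ADRs, plus the combined share of
    the three target SOCs."""
    grand = counts.total("total")
    if grand == 0:
        raise ValueError("count table has zero grand total")
    combined = sum(counts.count("total", s) for s in TARGET_SOCS)
    rows = []
    for soc in SocCategory:
        k = counts.count("total", soc)
        rows.append({
            "soc": soc.value,
            "count": k,
            "percent_of_all": round_half_away(100.0 * k / grand, 1),
            "percent_of_target": (
                round_half_away(100.0 * k / combined, 1)
                if soc in TARGET_SOCS and combined else None
            ),
        })
    rows.append({
        "soc": "target_socs_combined",
        "count": combined,
        "percent_of_all": round_half_away(100.0 * combined / grand, 1),
        "percent_of_target": 100.0 if combined else None,
    })
    return pd.DataFrame(rows)


def adrs_per_icsr(n_adrs: int, n_icsrs: int) -> float:
    """Mean suspected ADRs per report, displayed at one decimal."""
    if n_icsrs <= 0:
        raise ValueError("n_icsrs must be positive")
    return round_half_away(n_adrs / n_icsrs, 1)


_TTE_GROUPS = (SocGroup.NERVOUS, SocGroup.MUSCULOSKELETAL,
               SocGroup.PSYCHIATRIC, SocGroup.MULTIPLE)


def tte_distribution(icsrs: Iterable[ICSR]) -> pd.DataFrame:
    """Boxplot-ready five-number summaries (min, Q1, median, Q3, max) of the
    time to onset, one row per SOC group; groups without any valid latency
    are omitted."""
    latencies: dict[SocGroup, list[int]] = {g: [] for g in _TTE_GROUPS}
    for icsr in icsrs:
        group = classify_icsr_soc_group(icsr)
        if group not in latencies:
            continue
        days = icsr_time_to_event(icsr, group)
        if days is not None:
            latencies[group].append(days)
    rows = []
    for group in _TTE_GROUPS:
        values = latencies[group]
        if not values:
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append({
            "soc_group": group.value,
            "n": len(values),
            "min": float(min(values)),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(max(values)),
        })
    return pd.DataFrame(rows, columns=["soc_group", "n", "min", "q1", "median", "q3", "max"])
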
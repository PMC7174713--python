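"""Case-by-case evaluation of ICSRs.

Three assessments, applied report by report:

* **Naranjo causality scoring** — the 10-question weighted probability
  scale; answers are yes / no / unknown, "unknown" always scores 0 and the
  total maps to doubtful (<= 0), possible (1-4), probable (5-8) or
  definite (>= 9).
* **Risk-factor screening** — the six regulatory risk factors for
  quinolone musculoskeletal / neurological / psychiatric toxicity: age
  over 60 years, renal failure, organ transplantation, corticosteroid use,
  history of previous side effects to quinolones, and use for a
  non-approved (not severe) therapeutic indication.
* **Time to onset** — days from start of suspect-drug therapy to
  adverse-event onset.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import AbstractSet, Iterable, Optional, Sequence

import pandas as pd

from .icsr import ICSR, SocGroup, TARGET_SOCS, classify_icsr_soc_group, normalize_term

logger = logging.getLogger(__name__)

__all__ = [
    "Causality",
    "CausalityAssessment",
    "RiskFactor",
    "RiskFactorProfile",
    "NARANJO_WEIGHTS",
    "naranjo_score",
    "flag_risk_factors",
    "time_to_event",
    "risk_factor_crosstab",
    "evaluate_cases",
    "load_non_approved_indications",
    "NegativeLatencyError",
]


class NegativeLatencyError(ValueError):
    """Adverse-event onset precedes the start of therapy."""


class Causality(str, Enum):
    DEFINITE = "definite"   # the scale's "certain"; >= 9
    PROBABLE = "probable"   # 5-8
    POSSIBLE = "possible"   # 1-4
    DOUBTFUL = "doubtful"   # <= 0 (rendered "Doubt" in some reports)


#: Per-question (yes, no, unknown) weights of the published 10-item scale.
#: Q1 prior conclusive reports; Q2 event after suspect drug; Q3 improved on
#: withdrawal; Q4 reappeared on rechallenge; Q5 alternative causes; Q6
#: placebo reaction; Q7 toxic drug concentration; Q8 dose-response; Q9
#: previous similar reaction; Q10 objective confirmation.
NARANJO_WEIGHTS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (2, -1, 0),
    (1, 0, 0),
    (2, -1, 0),
    (-1, 2, 0),
    (-1, 1, 0),
    (1, 0, 0),
    (1, 0, 0),
    (1, 0, 0),
    (1, 0, 0),
)

_ANSWER_INDEX = {"yes": 0, "no": 1, "unknown": 2}


@dataclass(frozen=True)
class CausalityAssessment:
    answers: tuple[str, ...]
    score: int
    category: Causality


def naranjo_score(answers: Sequence[str]) -> CausalityAssessment:
    """Score a 10-answer vector and classify it.

    Category boundaries: score >= 9 definite, 5-8 probable, 1-4 possible,
    <= 0 doubtful.
    """
    if len(answers) != 10:
        raise ValueError(f"expected 10 answers, got {len(answers)}")
    normalized = tuple(a.strip().lower() for a in answers)
    bad = [a for a in normalized if a not in _ANSWER_INDEX]
    if bad:
        raise ValueError(f"invalid answer tokens {bad}; use yes/no/unknown")
    score = sum(
        NARANJO_WEIGHTS[q][_ANSWER_INDEX[a]] for q, a in enumerate(normalized)
    )
    if score >= 9:
        category = Causality.DEFINITE
    elif score >= 5:
        category = Causality.PROBABLE
    elif score >= 1:
        category = Causality.POSSIBLE
    else:
        category = Causality.DOUBTFUL
    return CausalityAssessment(normalized, score, category)


class RiskFactor(str, Enum):
    AGE_OVER_60 = "age_over_60"
    RENAL_FAILURE = "renal_failure"
    ORGAN_TRANSPLANTATION = "organ_transplantation"
    CORTICOSTEROID_USE = "corticosteroid_use"
    HISTORY_OF_SIDE_EFFECTS = "history_of_side_effects"
    THERAPEUTIC_INDICATION = "therapeutic_indication"


@dataclass(frozen=True)
class RiskFactorProfile:
    flags: frozenset[RiskFactor]

    @property
    def n_flags(self) -> int:
        return len(self.flags)


def load_non_approved_indications() -> frozenset[str]:
    """The packaged default list of non-approved (not severe) indications."""
    ref = resources.files("quinpv.data").joinpath("non_approved_indications.txt")
    with ref.open("r", encoding="utf-8") as fh:
        return frozenset(normalize_term(line) for line in fh if line.strip())


def flag_risk_factors(
    icsr: ICSR,
    approved_indications: AbstractSet[str] = frozenset(),
    age_threshold_years: float = 60,
) -> RiskFactorProfile:
    """Screen one report against the six risk factors.

    The age flag requires age strictly greater than the threshold; a
    missing age never sets it.  The therapeutic-indication flag is set when
    a suspect's indication, normalized, is absent from the approved list
    (reports without any recorded indication are not flagged).
    """
    flags: set[RiskFactor] = set()
    if icsr.age_years is None:
        logger.debug("%s: age missing, age flag not evaluated", icsr.report_id)
    elif icsr.age_years > age_threshold_years:
        flags.add(RiskFactor.AGE_OVER_60)
    if "renal_failure" in icsr.comorbidities:
        flags.add(RiskFactor.RENAL_FAILURE)
    if "organ_transplantation" in icsr.comorbidities:
        flags.add(RiskFactor.ORGAN_TRANSPLANTATION)
    if icsr.concomitant_corticosteroid:
        flags.add(RiskFactor.CORTICOSTEROID_USE)
    if icsr.prior_quinolone_reaction:
        flags.add(RiskFactor.HISTORY_OF_SIDE_EFFECTS)
    approved = {normalize_term(t) for t in approved_indications}
    for suspect in icsr.suspects:
        if suspect.indication and normalize_term(suspect.indication) not in approved:
            flags.add(RiskFactor.THERAPEUTIC_INDICATION)
            break
    return RiskFactorProfile(frozenset(flags))


def time_to_event(therapy_start: dt.date, onset: dt.date) -> int:
    """Whole days from therapy start to event onset; 0 means same-day."""
    days = (onset - therapy_start).days
    if days < 0:
        raise NegativeLatencyError(
            f"onset {onset} precedes therapy start {therapy_start}"
        )
    return days


def icsr_time_to_event(icsr: ICSR, group: Optional[SocGroup] = None) -> Optional[int]:
    """Latency of a report: earliest onset among its target-SOC events minus
    the earliest therapy start.  Returns None when dates are missing;
    records with a negative latency are flagged and excluded (None)."""
    starts = [s.therapy_start_date for s in icsr.suspects if s.therapy_start_date]
    if group is None:
        group = classify_icsr_soc_group(icsr)
    onsets = [
        e.onset_date
        for e in icsr.events
        if e.onset_date is not None and e.soc in TARGET_SOCS
    ]
    if not starts or not onsets:
        return None
    try:
        return time_to_event(min(starts), min(onsets))
    except NegativeLatencyError:
        logger.warning("%s: negative latency, excluded from summaries", icsr.report_id)
        return None


_CROSSTAB_GROUPS = (
    SocGroup.MUSCULOSKELETAL,
    SocGroup.PSYCHIATRIC,
    SocGroup.NERVOUS,
    SocGroup.MULTIPLE,
)


def risk_factor_crosstab(
    icsrs: Iterable[ICSR],
    approved_indications: AbstractSet[str] = frozenset(),
    age_threshold_years: float = 60,
) -> pd.DataFrame:
    """SOC group x risk factor counts (an ICSR contributes one count per
    flag), with per-row totals and a grand-total row.

    Includes two bookkeeping columns: ``flagged_icsrs`` (reports with at
    least one flag) and ``total_flags``.
    """
    factor_cols = [f.value for f in RiskFactor]
    data = {g: {c: 0 for c in factor_cols} for g in _CROSSTAB_GROUPS}
    flagged = {g: 0 for g in _CROSSTAB_GROUPS}
    for icsr in icsrs:
        group = classify_icsr_soc_group(icsr)
        if group not in data:
            continue
        profile = flag_risk_factors(icsr, approved_indications, age_threshold_years)
        for flag in profile.flags:
            data[group][flag.value] += 1
        if profile.n_flags:
            flagged[group] += 1
    rows = []
    for g in _CROSSTAB_GROUPS:
        row = {"soc_group": g.value, **data[g]}
        row["total_flags"] = sum(data[g].values())
        row["flagged_icsrs"] = flagged[g]
        rows.append(row)
    total = {
        "soc_group": "total",
        **{c: sum(data[g][c] for g in _CROSSTAB_GROUPS) for c in factor_cols},
    }
    total["total_flags"] = sum(r["total_flags"] for r in rows)
    total["flagged_icsrs"] = sum(r["flagged_icsrs"] for r in rows)
    rows.append(total)
    return pd.DataFrame(rows, columns=["soc_group"] + factor_cols + ["total_flags", "flagged_icsrs"])


def evaluate_cases(
    icsrs: Iterable[ICSR],
    approved_indications: AbstractSet[str] = frozenset(),
    age_threshold_years: float = 60,
) -> pd.DataFrame:
    """Per-report evaluation table: SOC group, Naranjo score and category,
    risk-factor flags and time to event (days)."""
    rows = []
    for icsr in icsrs:
        group = classify_icsr_soc_group(icsr)
        if icsr.naranjo_answers is not None:
            assessment = naranjo_score(icsr.naranjo_answers)
            score: Optional[int] = assessment.score
            causality: Optional[str] = assessment.category.value
        else:
            score = causality = None
        profile = flag_risk_factors(icsr, approved_indications, age_threshold_years)
        rows.append(
            {
                "report_id": icsr.report_id,
                "soc_group": group.value,
                "naranjo_score": score,
                "causality": causality,
                "n_risk_factors": profile.n_flags,
                "risk_factors": ";".join(sorted(f.value for f in profile.flags)),
                "time_to_event_days": icsr_time_to_event(icsr, group),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "report_id", "soc_group", "naranjo_score", "causality",
            "n_risk_factors", "risk_factors", "time_to_event_days",
        ],
    )
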
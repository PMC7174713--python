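"""Synthetic ICSR generator with known ground-truth reporting-odds structure.

The national and regional spontaneous-reporting datasets behind this kind of
analysis are not publicly distributable, so every downstream stage is
exercised on simulated line listings whose signal structure is known
exactly.  Each simulated report draws

* a suspected quinolone from a drug mix (default: the national reporting
  frequencies),
* a number of adverse events from a zero-truncated Poisson (default mean
  1.8 events per report),
* each event's SOC from a generation-specific categorical distribution
  built so that the odds of each target SOC versus everything else equal
  ``theta * baseline_odds`` — making the configured odds multipliers
  exactly the estimand of the ROR engine,
* a preferred term uniformly from the dictionary entries of that SOC,
* onset = therapy start + a geometric latency with a per-SOC mean,
* demographics, seriousness, outcome, reporter and risk-factor context
  from categorical/Bernoulli draws calibrated to the study populations.

All randomness flows through one numpy ``Generator`` (PCG64) seeded from
the config, so equal seeds give byte-identical line listings.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .icsr import (
    ICSR,
    AdverseEvent,
    CountTable,
    Gender,
    Outcome,
    QUINOLONE_CATALOG,
    Reporter,
    Seriousness,
    SocCategory,
    SuspectDrug,
    TARGET_SOCS,
    load_pt_dictionary,
    load_table1_counts,
)

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate",
    "simulate_generation_counts",
    "ground_truth_ror",
    "soc_probs_for_generation",
    "write_ground_truth",
    "APPROVED_INDICATION_POOL",
    "NON_APPROVED_INDICATIONS",
]

_SOC_ORDER = list(SocCategory)

#: Indications the generator treats as on-label (a plain pool, not a
#: clinical statement); the case-evaluation screen receives this set as the
#: approved list when evaluating simulated data.
APPROVED_INDICATION_POOL = (
    "urinary tract infection",
    "pneumonia",
    "acute bronchitis",
    "cystitis",
    "bacterial sinusitis",
    "pyelonephritis",
)


def _load_non_approved() -> tuple[str, ...]:
    from importlib import resources

    ref = resources.files("quinpv.data").joinpath("non_approved_indications.txt")
    with ref.open("r", encoding="utf-8") as fh:
        return tuple(line.strip() for line in fh if line.strip())


NON_APPROVED_INDICATIONS = _load_non_approved()

#: Background preferred terms for events outside the three target SOCs.
_OTHER_PTS = (
    "nausea", "vomiting", "diarrhoea", "rash", "urticaria", "pruritus",
    "abdominal pain", "hepatitis", "electrocardiogram qt prolonged",
    "photosensitivity reaction",
)

# Naranjo answer templates steering the simulated causality mix
# (possible / probable / doubtful ~ 59 / 40 / 1 percent of reports).
_NARANJO_TEMPLATES = (
    ["unknown", "yes"] + ["unknown"] * 8,                      # score 2, possible
    ["yes", "yes", "yes", "unknown", "no"] + ["unknown"] * 5,  # score 6, probable
    ["unknown", "no"] + ["unknown"] * 8,                       # score -1, doubtful
)
_NARANJO_TEMPLATE_PROBS = (0.59, 0.40, 0.01)


@dataclass
class GeneratorConfig:
    """All knobs of the simulator, with defaults set to the study conditions
    (see :func:`default_config` for how they are derived)."""

    n_icsrs: int
    seed: int
    drug_mix: dict[str, float]
    baseline_soc_probs: dict[SocCategory, float]
    soc_odds_multiplier: dict[tuple[int, SocCategory], float] = field(default_factory=dict)
    events_per_icsr_mean: float = 1.8
    latency_mean_days: dict[SocCategory, float] = field(
        default_factory=lambda: {
            SocCategory.NERVOUS: 1.0,
            SocCategory.MUSCULOSKELETAL: 3.0,
            SocCategory.PSYCHIATRIC: 3.0,
            SocCategory.OTHER: 2.0,
        }
    )
    age_loc: float = 54.0
    age_scale: float = 25.0
    age_range: tuple[float, float] = (0.0, 100.0)
    age_missing_prob: float = 0.083
    gender_probs: dict[Gender, float] = field(
        default_factory=lambda: {Gender.FEMALE: 0.51, Gender.MALE: 0.41, Gender.UNKNOWN: 0.08}
    )
    risk_factor_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "renal_failure": 0.034,
            "organ_transplantation": 0.023,
            "concomitant_corticosteroid": 0.023,
            "prior_quinolone_reaction": 0.011,
            "off_label_indication": 0.115,
        }
    )
    seriousness_probs: dict[Seriousness, float] = field(
        default_factory=lambda: {
            Seriousness.NOT_SERIOUS: 0.654,
            Seriousness.SERIOUS_HOSPITALIZATION: 0.149,
            Seriousness.SERIOUS_CLINICALLY_SIGNIFICANT: 0.129,
            Seriousness.SERIOUS_LIFE_THREATENING: 0.020,
            Seriousness.SERIOUS_DISABILITY: 0.018,
            Seriousness.SERIOUS_DEATH: 0.005,
            Seriousness.NOT_DEFINED: 0.025,
        }
    )
    outcome_probs: dict[Outcome, float] = field(
        default_factory=lambda: {
            Outcome.RECOVERED: 0.398,
            Outcome.IMPROVEMENT: 0.396,
            Outcome.UNCHANGED: 0.057,
            Outcome.NOT_AVAILABLE: 0.118,
            Outcome.DEATH: 0.007,
            Outcome.RESOLUTION_WITH_SEQUELAE: 0.024,
        }
    )
    reporter_probs: dict[Reporter, float] = field(
        default_factory=lambda: {
            Reporter.PHYSICIAN: 0.548,
            Reporter.PHARMACIST: 0.176,
            Reporter.OTHER_HCP: 0.172,
            Reporter.PATIENT: 0.104,
        }
    )
    multi_suspect_prob: float = 0.149
    study_window: tuple[dt.date, dt.date] = (dt.date(2002, 1, 1), dt.date(2019, 3, 31))

    def validate(self) -> None:
        problems = []
        if self.n_icsrs < 1:
            problems.append("n_icsrs must be >= 1")
        for name, probs in [
            ("drug_mix", self.drug_mix),
            ("baseline_soc_probs", self.baseline_soc_probs),
            ("gender_probs", self.gender_probs),
            ("seriousness_probs", self.seriousness_probs),
            ("outcome_probs", self.outcome_probs),
            ("reporter_probs", self.reporter_probs),
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                problems.append(f"{name} sums to {total!r}, not 1")
            if any(p < 0 for p in probs.values()):
                problems.append(f"{name} has negative entries")
        for drug in self.drug_mix:
            if drug not in QUINOLONE_CATALOG:
                problems.append(f"drug_mix drug {drug!r} not in catalog")
        for (gen, soc), theta in self.soc_odds_multiplier.items():
            if theta <= 0:
                problems.append(f"theta for (gen{gen}, {soc.value}) must be > 0")
            if soc not in TARGET_SOCS:
                problems.append(f"odds multiplier target {soc.value} is not a target SOC")
        if self.events_per_icsr_mean <= 1.0:
            problems.append("events_per_icsr_mean must exceed 1 (zero-truncated Poisson)")
        for soc, m in self.latency_mean_days.items():
            if m < 0:
                problems.append(f"latency mean for {soc.value} must be >= 0")
        if not problems:
            for gen in (1, 2, 3, 4):
                try:
                    soc_probs_for_generation(self, gen)
                except ValueError as exc:
                    problems.append(str(exc))
        if self.study_window[0] > self.study_window[1]:
            problems.append("study_window start after end")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))

    def theta(self, generation: int, soc: SocCategory) -> float:
        return self.soc_odds_multiplier.get((generation, soc), 1.0)


def default_config(n_icsrs: int = 5000, seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions.

    The drug mix follows the national reporting frequencies; the baseline
    SOC distribution is the second generation's observed SOC shares; the
    per-generation odds multipliers are the empirical odds ratios of the
    national count table against the second generation, so simulated data
    reproduce the reporting-odds structure of the real system.
    """
    counts = load_table1_counts()
    drug_mix = {
        "levofloxacin": 5941, "ciprofloxacin": 4498, "moxifloxacin": 820,
        "prulifloxacin": 245, "norfloxacin": 146, "lomefloxacin": 138,
        "ofloxacin": 81, "cinoxacin": 70, "pefloxacin": 51,
        "pipemidic acid": 47, "rufloxacin": 19, "nalidixic acid": 3,
    }
    n_total = sum(drug_mix.values())
    drug_mix = {k: v / n_total for k, v in drug_mix.items()}

    ref_total = counts.total("gen2")
    baseline = {soc: counts.count("gen2", soc) / ref_total for soc in _SOC_ORDER}

    def _odds(group: str, soc: SocCategory) -> float:
        k, t = counts.count(group, soc), counts.total(group)
        return k / (t - k)

    theta = {
        (gen, soc): _odds(f"gen{gen}", soc) / _odds("gen2", soc)
        for gen in (1, 3, 4)
        for soc in TARGET_SOCS
    }
    params = {
        "drug_mix": drug_mix,
        "baseline_soc_probs": baseline,
        "soc_odds_multiplier": theta,
    }
    params.update(overrides)
    cfg = GeneratorConfig(n_icsrs=n_icsrs, seed=seed, **params)
    cfg.validate()
    return cfg


def soc_probs_for_generation(config: GeneratorConfig, generation: int) -> np.ndarray:
    """Per-generation SOC probability vector.

    Each target SOC gets probability q = t / (1 + t) where
    t = theta * baseline_odds(SOC); the OTHER category absorbs the
    remainder.  This keeps the odds of every target SOC versus all else
    exactly theta * baseline_odds, so configured odds ratios are the exact
    estimand of the downstream ROR.
    """
    probs = {}
    for soc in TARGET_SOCS:
        p0 = config.baseline_soc_probs[soc]
        t = config.theta(generation, soc) * p0 / (1 - p0)
        probs[soc] = t / (1 + t)
    other = 1.0 - sum(probs.values())
    if other <= 0:
        raise ValueError(
            f"odds multipliers for generation {generation} leave no probability "
            "for the OTHER category"
        )
    probs[SocCategory.OTHER] = other
    return np.array([probs[s] for s in _SOC_ORDER])


def ground_truth_ror(
    config: GeneratorConfig, index_gen: int, ref_gen: int, soc: SocCategory
) -> float:
    """The odds ratio implied by the config: theta_index / theta_ref."""
    for gen in (index_gen, ref_gen):
        if gen not in (1, 2, 3, 4):
            raise KeyError(f"unknown generation {gen}")
    return config.theta(index_gen, soc) / config.theta(ref_gen, soc)


# ---------------------------------------------------------------------------
# Sampling


def _ztp_rate(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the requested mean."""
    return brentq(lambda lam: lam / (1 - math.exp(-lam)) - mean, 1e-9, 60.0)


def _sample_ztp(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    draws = rng.poisson(rate, size)
    while True:
        zero = draws == 0
        if not zero.any():
            return draws
        draws[zero] = rng.poisson(rate, int(zero.sum()))


def _sample_categorical(rng: np.random.Generator, probs: Mapping, size: int) -> list:
    keys = list(probs.keys())
    idx = rng.choice(len(keys), size=size, p=np.array([probs[k] for k in keys]))
    return [keys[i] for i in idx]


def _sample_truncated_normal(
    rng: np.random.Generator, loc: float, scale: float,
    lo: float, hi: float, size: int,
) -> np.ndarray:
    draws = rng.normal(loc, scale, size)
    while True:
        out = (draws < lo) | (draws > hi)
        if not out.any():
            return draws
        draws[out] = rng.normal(loc, scale, int(out.sum()))


def _sample_core(config: GeneratorConfig, rng: np.random.Generator):
    """Drug, generation, event-count and per-event SOC draws (the part of
    the model that determines the reporting-odds structure)."""
    drug_names = list(config.drug_mix.keys())
    drug_probs = np.array([config.drug_mix[d] for d in drug_names])
    drug_idx = rng.choice(len(drug_names), size=config.n_icsrs, p=drug_probs)
    generations = np.array([QUINOLONE_CATALOG[d].generation for d in drug_names])[drug_idx]

    rate = _ztp_rate(config.events_per_icsr_mean)
    n_events = _sample_ztp(rng, rate, config.n_icsrs)

    event_gen = np.repeat(generations, n_events)
    total_events = int(n_events.sum())
    u = rng.random(total_events)
    soc_idx = np.empty(total_events, dtype=np.int64)
    for gen in (1, 2, 3, 4):
        mask = event_gen == gen
        if not mask.any():
            continue
        cum = np.cumsum(soc_probs_for_generation(config, gen))
        soc_idx[mask] = np.searchsorted(cum, u[mask], side="right")
    return drug_idx, drug_names, generations, n_events, soc_idx


def simulate_generation_counts(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> CountTable:
    """Fast path: draw only the generation x SOC ADR counts (the sufficient
    statistic for the disproportionality stage), without materializing
    reports.  Used for replicate studies; same sampling distribution as
    :func:`generate`."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _, _, generations, n_events, soc_idx = _sample_core(config, rng)
    event_gen = np.repeat(generations, n_events)
    matrix = np.zeros((4, len(_SOC_ORDER)), dtype=np.int64)
    np.add.at(matrix, (event_gen - 1, soc_idx), 1)
    rows = []
    grand = np.zeros(len(_SOC_ORDER), dtype=np.int64)
    for gen in (1, 2, 3, 4):
        counts_row = matrix[gen - 1]
        grand += counts_row
        rec = {"group": f"gen{gen}", "level": "generation"}
        rec.update({s.value: int(c) for s, c in zip(_SOC_ORDER, counts_row)})
        rec["total"] = int(counts_row.sum())
        rows.append(rec)
    rec = {"group": "total", "level": "total"}
    rec.update({s.value: int(c) for s, c in zip(_SOC_ORDER, grand)})
    rec["total"] = int(grand.sum())
    rows.append(rec)
    table = CountTable(pd.DataFrame(rows))
    table.validate()
    return table


def ground_truth_record(config: GeneratorConfig) -> dict:
    """Exact per-generation SOC odds and implied pairwise RORs."""
    record = {
        "seed": config.seed,
        "n_icsrs": config.n_icsrs,
        "theta": {
            f"gen{gen}:{soc.value}": config.theta(gen, soc)
            for gen in (1, 2, 3, 4)
            for soc in TARGET_SOCS
        },
        "soc_probs": {
            f"gen{gen}": {
                soc.value: float(p)
                for soc, p in zip(_SOC_ORDER, soc_probs_for_generation(config, gen))
            }
            for gen in (1, 2, 3, 4)
        },
    }
    return record


def write_ground_truth(config: GeneratorConfig, dest: Union[str, IO[str]]) -> None:
    record = ground_truth_record(config)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        json.dump(record, dest, indent=2, sort_keys=True)
        dest.write("\n")


def generate(config: GeneratorConfig) -> tuple[list[ICSR], dict]:
    """Generate a full synthetic line listing plus its ground-truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    drug_idx, drug_names, generations, n_events, soc_idx = _sample_core(config, rng)

    dictionary = load_pt_dictionary()
    pts_by_soc = {soc: sorted(pt for pt, s in dictionary.items() if s == soc) for soc in _SOC_ORDER}
    pts_by_soc[SocCategory.OTHER] = list(_OTHER_PTS)

    window_start, window_end = config.study_window
    span = (window_end - window_start).days - 90
    start_offsets = rng.integers(0, max(span, 1), size=config.n_icsrs)

    ages = _sample_truncated_normal(
        rng, config.age_loc, config.age_scale, *config.age_range, config.n_icsrs
    )
    age_missing = rng.random(config.n_icsrs) < config.age_missing_prob
    genders = _sample_categorical(rng, config.gender_probs, config.n_icsrs)
    seriousness = _sample_categorical(rng, config.seriousness_probs, config.n_icsrs)
    outcomes = _sample_categorical(rng, config.outcome_probs, config.n_icsrs)
    reporters = _sample_categorical(rng, config.reporter_probs, config.n_icsrs)

    prev = config.risk_factor_prevalence
    renal = rng.random(config.n_icsrs) < prev.get("renal_failure", 0.0)
    transplant = rng.random(config.n_icsrs) < prev.get("organ_transplantation", 0.0)
    steroid = rng.random(config.n_icsrs) < prev.get("concomitant_corticosteroid", 0.0)
    prior = rng.random(config.n_icsrs) < prev.get("prior_quinolone_reaction", 0.0)
    off_label = rng.random(config.n_icsrs) < prev.get("off_label_indication", 0.0)
    multi = rng.random(config.n_icsrs) < config.multi_suspect_prob
    template_idx = rng.choice(
        len(_NARANJO_TEMPLATES), size=config.n_icsrs, p=np.array(_NARANJO_TEMPLATE_PROBS)
    )

    icsrs: list[ICSR] = []
    pos = 0
    width = len(str(config.n_icsrs))
    for i in range(config.n_icsrs):
        k = int(n_events[i])
        event_socs = [_SOC_ORDER[j] for j in soc_idx[pos:pos + k]]
        pos += k
        start = window_start + dt.timedelta(days=int(start_offsets[i]))
        events = []
        seen: set[tuple[str, dt.date]] = set()
        for soc in event_socs:
            mean = config.latency_mean_days.get(soc, 0.0)
            lat = int(rng.geometric(1.0 / (mean + 1.0)) - 1) if mean > 0 else 0
            onset = start + dt.timedelta(days=lat)
            pool = pts_by_soc[soc]
            # a report never lists the same term twice for the same day
            for _ in range(30):
                pt = pool[int(rng.integers(len(pool)))]
                if (pt, onset) not in seen:
                    break
            else:  # pool exhausted; drop the colliding extra event
                continue
            seen.add((pt, onset))
            events.append(AdverseEvent(pt, soc, onset))
        last_onset = max(e.onset_date for e in events)
        delay = int(rng.geometric(1.0 / 8.0) - 1)
        receive = min(last_onset + dt.timedelta(days=delay), window_end)
        if off_label[i]:
            indication = NON_APPROVED_INDICATIONS[int(rng.integers(len(NON_APPROVED_INDICATIONS)))]
        else:
            indication = APPROVED_INDICATION_POOL[int(rng.integers(len(APPROVED_INDICATION_POOL)))]
        comorbidities = set()
        if renal[i]:
            comorbidities.add("renal_failure")
        if transplant[i]:
            comorbidities.add("organ_transplantation")
        icsr = ICSR(
            report_id=f"SIM-{i + 1:0{width}d}",
            receive_date=receive,
            age_years=None if age_missing[i] else round(float(ages[i]), 1),
            gender=genders[i],
            reporter=reporters[i],
            seriousness=seriousness[i],
            outcome=outcomes[i],
            suspects=[
                SuspectDrug(
                    drug=QUINOLONE_CATALOG[drug_names[int(drug_idx[i])]],
                    therapy_start_date=start,
                    indication=indication,
                )
            ],
            events=events,
            comorbidities=comorbidities,
            concomitant_corticosteroid=bool(steroid[i]),
            prior_quinolone_reaction=bool(prior[i]),
            n_suspect_drugs_total=2 if multi[i] else 1,
            naranjo_answers=list(_NARANJO_TEMPLATES[int(template_idx[i])]),
        )
        icsr.validate()
        icsrs.append(icsr)

    truth = ground_truth_record(config)
    return icsrs, truth
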
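"""Domain model for spontaneous adverse-drug-reaction reports (ICSRs).

An Individual Case Safety Report (ICSR) describes one patient, one or more
suspected drugs and one or more adverse events (each coded by a MedDRA-style
preferred term, PT).  This module provides:

* the four-way System Organ Class (SOC) grouping used throughout the
  analysis (nervous / musculoskeletal / psychiatric / everything else),
* the quinolone catalog with its four-generation taxonomy,
* a PT -> SOC mini-dictionary shipped with the package,
* a CSV line-listing dialect (one row per suspected-drug / event pair) with
  reader and writer,
* aggregation of a line listing into a drug- or generation-level count
  table whose unit of counting is the ADR, i.e. the (suspected quinolone,
  adverse event) pair.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SocCategory",
    "SocGroup",
    "Gender",
    "Reporter",
    "Seriousness",
    "Outcome",
    "DrugEntry",
    "AdverseEvent",
    "SuspectDrug",
    "ICSR",
    "CountTable",
    "QUINOLONE_CATALOG",
    "TARGET_SOCS",
    "LineListingError",
    "DictionaryError",
    "DrugLookupError",
    "load_pt_dictionary",
    "map_pt_to_soc",
    "classify_generation",
    "normalize_term",
    "read_line_listing",
    "write_line_listing",
    "aggregate_counts",
    "classify_icsr_soc_group",
    "load_table1_counts",
    "parse_date",
    "LISTING_COLUMNS",
]


class LineListingError(ValueError):
    """Malformed line-listing input (missing column, bad date, duplicate row)."""


class DictionaryError(ValueError):
    """Invalid PT -> SOC dictionary input or empty query term."""


class DrugLookupError(KeyError):
    """A suspected drug is not in the quinolone catalog."""


class SocCategory(str, Enum):
    """The four-way SOC grouping of adverse events used by the analysis."""

    NERVOUS = "nervous"
    MUSCULOSKELETAL = "musculoskeletal"
    PSYCHIATRIC = "psychiatric"
    OTHER = "other"


#: The three SOCs whose reporting probability is under study.
TARGET_SOCS = (
    SocCategory.NERVOUS,
    SocCategory.MUSCULOSKELETAL,
    SocCategory.PSYCHIATRIC,
)


class SocGroup(str, Enum):
    """Report-level SOC classification: the single target SOC represented,
    MULTIPLE when events span >= 2 distinct target SOCs, NONE otherwise."""

    NERVOUS = "nervous"
    MUSCULOSKELETAL = "musculoskeletal"
    PSYCHIATRIC = "psychiatric"
    MULTIPLE = "multiple"
    NONE = "none"


class Gender(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Reporter(str, Enum):
    PHYSICIAN = "physician"
    PHARMACIST = "pharmacist"
    OTHER_HCP = "other_hcp"
    PATIENT = "patient"


class Seriousness(str, Enum):
    """ICH E2D-style seriousness coding of a report."""

    NOT_SERIOUS = "not_serious"
    SERIOUS_CLINICALLY_SIGNIFICANT = "serious_clinically_significant"
    SERIOUS_DEATH = "serious_death"
    SERIOUS_DISABILITY = "serious_disability"
    SERIOUS_HOSPITALIZATION = "serious_hospitalization"
    SERIOUS_LIFE_THREATENING = "serious_life_threatening"
    NOT_DEFINED = "not_defined"


class Outcome(str, Enum):
    RECOVERED = "recovered"
    IMPROVEMENT = "improvement"
    RESOLUTION_WITH_SEQUELAE = "resolution_with_sequelae"
    UNCHANGED = "unchanged"
    DEATH = "death"
    NOT_AVAILABLE = "not_available"


# ---------------------------------------------------------------------------
# Drug catalog


@dataclass(frozen=True)
class DrugEntry:
    """A quinolone with its generation (1-4) in the four-class taxonomy."""

    name: str
    generation: int

    def __post_init__(self) -> None:
        if self.generation not in (1, 2, 3, 4):
            raise ValueError(f"generation must be 1-4, got {self.generation}")


#: Quinolones by generation of antimicrobial spectrum.
QUINOLONE_CATALOG: Mapping[str, DrugEntry] = {
    name: DrugEntry(name, gen)
    for gen, names in {
        1: ("nalidixic acid", "pipemidic acid", "cinoxacin", "flumequine"),
        2: ("enoxacin", "lomefloxacin", "ciprofloxacin", "norfloxacin",
            "ofloxacin", "rufloxacin"),
        3: ("levofloxacin", "moxifloxacin", "pefloxacin"),
        4: ("prulifloxacin",),
    }.items()
    for name in names
}


def normalize_term(text: str) -> str:
    """Lowercase and collapse internal whitespace (the matching key for PTs,
    drug names and indications)."""
    return " ".join(text.split()).lower()


def classify_generation(
    drug_name: str,
    catalog: Optional[Mapping[str, DrugEntry]] = None,
) -> int:
    """Return the generation (1-4) of a quinolone, matching case- and
    whitespace-insensitively.

    Raises
    ------
    DrugLookupError
        If the normalized name is not in the catalog.
    """
    catalog = QUINOLONE_CATALOG if catalog is None else catalog
    key = normalize_term(drug_name)
    try:
        return catalog[key].generation
    except KeyError:
        raise DrugLookupError(key) from None


# ---------------------------------------------------------------------------
# PT -> SOC dictionary


def load_pt_dictionary(source: Union[str, IO[str], None] = None) -> dict[str, SocCategory]:
    """Load a two-column TSV (preferred_term, soc_code) into a normalized
    PT -> SocCategory map.  With no argument, the dictionary shipped with
    the package (covering the preferred terms of the regional case series)
    is loaded."""
    if source is None:
        ref = resources.files("quinpv.data").joinpath("pt_soc.tsv")
        with ref.open("r", encoding="utf-8") as fh:
            return load_pt_dictionary(fh)
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return load_pt_dictionary(fh)
    mapping: dict[str, SocCategory] = {}
    reader = csv.reader(source, delimiter="\t")
    header = next(reader, None)
    if header is None or [h.strip() for h in header[:2]] != ["preferred_term", "soc_code"]:
        raise DictionaryError("dictionary must have columns preferred_term, soc_code")
    for row in reader:
        if not row or not row[0].strip():
            continue
        pt, code = normalize_term(row[0]), row[1].strip().lower()
        try:
            soc = SocCategory(code)
        except ValueError:
            raise DictionaryError(f"unknown soc_code {code!r} for PT {pt!r}") from None
        mapping[pt] = soc
    return mapping


def map_pt_to_soc(pt: str, dictionary: Mapping[str, SocCategory]) -> SocCategory:
    """Map a preferred term to its SOC category; unlisted terms map to OTHER.

    Matching is case-insensitive on whitespace-normalized text; no fuzzy
    matching is attempted (a silent near-match would corrupt counts).
    """
    if not pt or not pt.strip():
        raise DictionaryError("empty preferred term")
    return dictionary.get(normalize_term(pt), SocCategory.OTHER)


# ---------------------------------------------------------------------------
# Records


@dataclass
class AdverseEvent:
    """One reported reaction: a preferred term, its SOC and optional onset."""

    preferred_term: str
    soc: SocCategory
    onset_date: Optional[dt.date] = None

    def validate(self) -> None:
        if not self.preferred_term.strip():
            raise ValueError("preferred_term must be non-empty")


@dataclass
class SuspectDrug:
    drug: DrugEntry
    therapy_start_date: Optional[dt.date] = None
    indication: Optional[str] = None

    def validate(self) -> None:
        if self.drug.name not in QUINOLONE_CATALOG:
            raise DrugLookupError(self.drug.name)


@dataclass
class ICSR:
    """One Individual Case Safety Report."""

    report_id: str
    receive_date: dt.date
    gender: Gender = Gender.UNKNOWN
    age_years: Optional[float] = None
    reporter: Optional[Reporter] = None
    seriousness: Seriousness = Seriousness.NOT_DEFINED
    outcome: Outcome = Outcome.NOT_AVAILABLE
    suspects: list[SuspectDrug] = field(default_factory=list)
    events: list[AdverseEvent] = field(default_factory=list)
    comorbidities: set[str] = field(default_factory=set)
    concomitant_corticosteroid: bool = False
    prior_quinolone_reaction: bool = False
    n_suspect_drugs_total: int = 1
    naranjo_answers: Optional[list[str]] = None

    def validate(self, study_window: Optional[tuple[dt.date, dt.date]] = None) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.suspects or not self.events:
            raise ValueError(f"{self.report_id}: at least one suspect and one event required")
        if self.age_years is not None and not (0 <= self.age_years < 150):
            raise ValueError(f"{self.report_id}: implausible age {self.age_years}")
        if self.n_suspect_drugs_total < len(self.suspects):
            raise ValueError(
                f"{self.report_id}: n_suspect_drugs_total below number of quinolone suspects"
            )
        if self.naranjo_answers is not None and len(self.naranjo_answers) != 10:
            raise ValueError(f"{self.report_id}: naranjo_answers must have 10 entries")
        for s in self.suspects:
            s.validate()
        for e in self.events:
            e.validate()
        if study_window is not None:
            lo, hi = study_window
            for d in self._all_dates():
                if not (lo <= d <= hi):
                    raise ValueError(
                        f"{self.report_id}: date {d} outside study window [{lo}, {hi}]"
                    )

    def _all_dates(self) -> Iterable[dt.date]:
        yield self.receive_date
        for s in self.suspects:
            if s.therapy_start_date is not None:
                yield s.therapy_start_date
        for e in self.events:
            if e.onset_date is not None:
                yield e.onset_date

    @property
    def generations(self) -> set[int]:
        return {s.drug.generation for s in self.suspects}


def classify_icsr_soc_group(icsr: ICSR) -> SocGroup:
    """Report-level classification: NONE if no event falls in a target SOC,
    the single SOC if exactly one target SOC is represented, MULTIPLE if the
    report's events span two or more distinct target SOCs."""
    present = {e.soc for e in icsr.events if e.soc in TARGET_SOCS}
    if not present:
        return SocGroup.NONE
    if len(present) > 1:
        return SocGroup.MULTIPLE
    return SocGroup(next(iter(present)).value)


# ---------------------------------------------------------------------------
# Line-listing I/O

#: Canonical column order of the CSV line-listing dialect.
LISTING_COLUMNS = [
    "report_id", "receive_date", "age_years", "gender", "reporter",
    "seriousness", "outcome", "drug", "generation", "therapy_start_date",
    "indication", "preferred_term", "onset_date", "renal_failure",
    "organ_transplantation", "concomitant_corticosteroid",
    "prior_quinolone_reaction", "n_suspect_drugs_total",
] + [f"naranjo_q{i}" for i in range(1, 11)]

_MISSING_TOKENS = {"", "na", "n/a"}
_TRUE_TOKENS = {"yes", "true", "1", "y"}
_FALSE_TOKENS = {"no", "false", "0", "n"}


def _is_missing(value: Optional[str]) -> bool:
    return value is None or value.strip().lower() in _MISSING_TOKENS


def parse_date(value: str, *, line: Optional[int] = None) -> Optional[dt.date]:
    """Parse an ISO-8601 date; empty / NA tokens give None."""
    if _is_missing(value):
        return None
    try:
        return dt.date.fromisoformat(value.strip())
    except ValueError:
        where = f" (line {line})" if line is not None else ""
        raise LineListingError(f"unparsable date {value!r}{where}") from None


def _parse_bool(value: Optional[str]) -> bool:
    if _is_missing(value):
        return False
    token = value.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise LineListingError(f"unparsable boolean {value!r}")


def read_line_listing(
    source: Union[str, IO[str]],
    dictionary: Optional[Mapping[str, SocCategory]] = None,
    catalog: Optional[Mapping[str, DrugEntry]] = None,
    *,
    permissive: bool = False,
    study_window: Optional[tuple[dt.date, dt.date]] = None,
) -> list[ICSR]:
    """Read a CSV line listing (one row per suspected-drug / event pair) and
    merge rows sharing a report_id into ICSRs.

    Unknown preferred terms map to OTHER with a logged warning.  Unknown
    drugs raise :class:`DrugLookupError` unless ``permissive`` is set, in
    which case the offending rows are skipped and counted in the log.  With
    a ``study_window`` (closed interval on receive_date) out-of-window
    reports are dropped.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_line_listing(
                fh, dictionary, catalog, permissive=permissive, study_window=study_window
            )
    dictionary = load_pt_dictionary() if dictionary is None else dictionary
    catalog = QUINOLONE_CATALOG if catalog is None else catalog

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return []
    for required in ("report_id", "receive_date", "drug", "preferred_term"):
        if required not in reader.fieldnames:
            raise LineListingError(f"missing required column {required!r}")

    icsrs: dict[str, ICSR] = {}
    seen_rows: set[tuple] = set()
    unknown_pts: set[str] = set()
    n_skipped = 0

    for lineno, row in enumerate(reader, start=2):
        rid = (row.get("report_id") or "").strip()
        if not any(not _is_missing(v) for v in row.values()):
            continue
        for required in ("report_id", "receive_date", "drug", "preferred_term"):
            if _is_missing(row.get(required)):
                raise LineListingError(f"empty {required!r} (line {lineno})")
        drug_key = normalize_term(row["drug"])
        if drug_key not in catalog:
            if permissive:
                n_skipped += 1
                continue
            raise DrugLookupError(drug_key)
        onset = parse_date(row.get("onset_date", ""), line=lineno)
        dedup_key = (rid, drug_key, normalize_term(row["preferred_term"]), onset)
        if dedup_key in seen_rows:
            raise LineListingError(
                f"duplicate (report_id, drug, preferred_term, onset_date) row (line {lineno})"
            )
        seen_rows.add(dedup_key)

        pt_key = normalize_term(row["preferred_term"])
        if pt_key not in dictionary:
            unknown_pts.add(pt_key)
        soc = map_pt_to_soc(row["preferred_term"], dictionary)

        if rid not in icsrs:
            receive = parse_date(row["receive_date"], line=lineno)
            age = None if _is_missing(row.get("age_years")) else float(row["age_years"])
            gender = (
                Gender.UNKNOWN if _is_missing(row.get("gender"))
                else Gender(row["gender"].strip().lower())
            )
            reporter = (
                None if _is_missing(row.get("reporter"))
                else Reporter(row["reporter"].strip().lower())
            )
            seriousness = (
                Seriousness.NOT_DEFINED if _is_missing(row.get("seriousness"))
                else Seriousness(row["seriousness"].strip().lower())
            )
            outcome = (
                Outcome.NOT_AVAILABLE if _is_missing(row.get("outcome"))
                else Outcome(row["outcome"].strip().lower())
            )
            comorbidities = set()
            if _parse_bool(row.get("renal_failure")):
                comorbidities.add("renal_failure")
            if _parse_bool(row.get("organ_transplantation")):
                comorbidities.add("organ_transplantation")
            answers = [
                (row.get(f"naranjo_q{i}") or "").strip().lower() for i in range(1, 11)
            ]
            naranjo = None if all(a in _MISSING_TOKENS for a in answers) else [
                a if a not in _MISSING_TOKENS else "unknown" for a in answers
            ]
            icsrs[rid] = ICSR(
                report_id=rid,
                receive_date=receive,
                age_years=age,
                gender=gender,
                reporter=reporter,
                seriousness=seriousness,
                outcome=outcome,
                comorbidities=comorbidities,
                concomitant_corticosteroid=_parse_bool(row.get("concomitant_corticosteroid")),
                prior_quinolone_reaction=_parse_bool(row.get("prior_quinolone_reaction")),
                n_suspect_drugs_total=(
                    1 if _is_missing(row.get("n_suspect_drugs_total"))
                    else int(row["n_suspect_drugs_total"])
                ),
                naranjo_answers=naranjo,
            )
        icsr = icsrs[rid]
        if drug_key not in {s.drug.name for s in icsr.suspects}:
            icsr.suspects.append(
                SuspectDrug(
                    drug=catalog[drug_key],
                    therapy_start_date=parse_date(row.get("therapy_start_date", ""), line=lineno),
                    indication=None if _is_missing(row.get("indication")) else row["indication"].strip(),
                )
            )
        if (pt_key, onset) not in {(normalize_term(e.preferred_term), e.onset_date) for e in icsr.events}:
            icsr.events.append(AdverseEvent(row["preferred_term"].strip(), soc, onset))

    if unknown_pts:
        logger.warning("unlisted preferred terms mapped to OTHER: %s", sorted(unknown_pts))
    if n_skipped:
        logger.warning("skipped %d rows with non-catalog drugs (permissive mode)", n_skipped)

    result = list(icsrs.values())
    if study_window is not None:
        lo, hi = study_window
        result = [r for r in result if lo <= r.receive_date <= hi]
    for r in result:
        r.n_suspect_drugs_total = max(r.n_suspect_drugs_total, len(r.suspects))
        r.validate()
    return result


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_line_listing(icsrs: Sequence[ICSR], dest: Union[str, IO[str]]) -> None:
    """Write ICSRs back to the canonical CSV dialect, one row per
    (suspect, event) pair, in canonical column order."""
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_line_listing(icsrs, fh)
            return
    writer = csv.DictWriter(dest, fieldnames=LISTING_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for icsr in icsrs:
        answers = icsr.naranjo_answers or [""] * 10
        base = {
            "report_id": icsr.report_id,
            "receive_date": _fmt(icsr.receive_date),
            "age_years": _fmt(icsr.age_years),
            "gender": _fmt(icsr.gender),
            "reporter": _fmt(icsr.reporter),
            "seriousness": _fmt(icsr.seriousness),
            "outcome": _fmt(icsr.outcome),
            "renal_failure": _fmt("renal_failure" in icsr.comorbidities),
            "organ_transplantation": _fmt("organ_transplantation" in icsr.comorbidities),
            "concomitant_corticosteroid": _fmt(icsr.concomitant_corticosteroid),
            "prior_quinolone_reaction": _fmt(icsr.prior_quinolone_reaction),
            "n_suspect_drugs_total": _fmt(icsr.n_suspect_drugs_total),
            **{f"naranjo_q{i}": answers[i - 1] for i in range(1, 11)},
        }
        for suspect in icsr.suspects:
            for event in icsr.events:
                writer.writerow({
                    **base,
                    "drug": suspect.drug.name,
                    "generation": suspect.drug.generation,
                    "therapy_start_date": _fmt(suspect.therapy_start_date),
                    "indication": _fmt(suspect.indication),
                    "preferred_term": event.preferred_term,
                    "onset_date": _fmt(event.onset_date),
                })


# ---------------------------------------------------------------------------
# Count tables

_SOC_COLUMNS = {
    SocCategory.NERVOUS: "nervous",
    SocCategory.MUSCULOSKELETAL: "musculoskeletal",
    SocCategory.PSYCHIATRIC: "psychiatric",
    SocCategory.OTHER: "other",
}
_COUNT_COLUMNS = ["group", "level"] + list(_SOC_COLUMNS.values()) + ["total"]


@dataclass
class CountTable:
    """ADR counts per group (drug / generation / grand total) and SOC.

    ``df`` has columns group, level, nervous, musculoskeletal, psychiatric,
    other, total.  Hierarchy is positional: drug rows following a generation
    row are its members.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        self.df = self.df[_COUNT_COLUMNS].reset_index(drop=True)

    def validate(self, check_hierarchy: bool = True) -> None:
        soc_cols = list(_SOC_COLUMNS.values())
        sums = self.df[soc_cols].sum(axis=1)
        bad = self.df.loc[sums != self.df["total"], "group"]
        if len(bad):
            raise ValueError(f"row total mismatch for groups {list(bad)}")
        if (self.df[soc_cols + ["total"]] < 0).any().any():
            raise ValueError("negative counts")
        if check_hierarchy:
            self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        cols = list(_SOC_COLUMNS.values()) + ["total"]
        gen_sum = pd.Series(0, index=cols)
        current: Optional[str] = None
        member_sum = pd.Series(0, index=cols)
        for _, row in self.df.iterrows():
            if row["level"] == "generation":
                self._flush(current, member_sum)
                current, member_sum = row["group"], pd.Series(0, index=cols)
                gen_sum = gen_sum + row[cols]
            elif row["level"] == "drug":
                member_sum = member_sum + row[cols]
            elif row["level"] == "total":
                self._flush(current, member_sum)
                current = None
                if not (gen_sum == row[cols]).all():
                    raise ValueError("grand total does not equal sum of generation rows")
        self._flush(current, member_sum)

    def _flush(self, group: Optional[str], member_sum: pd.Series) -> None:
        if group is None or not member_sum.any():
            return
        cols = list(_SOC_COLUMNS.values()) + ["total"]
        row = self.df.loc[self.df["group"] == group, cols].iloc[0]
        if not (row == member_sum).all():
            raise ValueError(f"generation row {group!r} does not equal sum of member drugs")

    # -- access -----------------------------------------------------------
    def groups(self, level: Optional[str] = None) -> list[str]:
        df = self.df if level is None else self.df[self.df["level"] == level]
        return list(df["group"])

    def _row(self, group: str) -> pd.Series:
        rows = self.df[self.df["group"] == group]
        if rows.empty:
            raise KeyError(group)
        return rows.iloc[0]

    def count(self, group: str, soc: SocCategory) -> int:
        return int(self._row(group)[_SOC_COLUMNS[soc]])

    def total(self, group: str) -> int:
        return int(self._row(group)["total"])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, source: Union[str, IO[str]], *, check_hierarchy: bool = True
    ) -> "CountTable":
        df = pd.read_csv(source, sep="\t")
        table = cls(df)
        table.validate(check_hierarchy=check_hierarchy)
        return table

    def to_tsv(self, dest: Union[str, IO[str]]) -> None:
        self.df.to_csv(dest, sep="\t", index=False, lineterminator="\n")


def load_table1_counts() -> CountTable:
    """The packaged transcription of the national drug x SOC ADR count table
    (the input to the generation-level disproportionality analysis).

    The published second-generation drug rows sum to 100 more other-SOC
    ADRs than the published generation row (8,388 vs 8,288 total); the
    generation rows are what the published pairwise comparisons use, so the
    transcription is kept verbatim and the drug-row hierarchy check is
    skipped for this table.
    """
    ref = resources.files("quinpv.data").joinpath("table1_counts.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return CountTable.from_tsv(fh, check_hierarchy=False)


def aggregate_counts(
    icsrs: Sequence[ICSR],
    level: str = "generation",
    *,
    attribution: str = "per_suspect",
) -> CountTable:
    """Aggregate a line listing into a hierarchical count table.

    The unit of counting is the ADR: the (suspected quinolone, adverse
    event) pair.  With ``attribution="per_suspect"`` (default) every event
    of a report contributes one count for every suspected quinolone in that
    report; ``"per_report"`` counts each event once per distinct generation
    among the report's suspects (multi-generation reports are logged).

    ``level="drug"`` emits drug rows nested under generation rows plus the
    grand total; ``level="generation"`` emits generation rows and the total.
    """
    if level not in ("drug", "generation"):
        raise ValueError(f"level must be 'drug' or 'generation', got {level!r}")
    if attribution not in ("per_suspect", "per_report"):
        raise ValueError(f"unknown attribution {attribution!r}")

    drug_counts: dict[str, dict[SocCategory, int]] = {}
    gen_counts: dict[int, dict[SocCategory, int]] = {g: {s: 0 for s in SocCategory} for g in (1, 2, 3, 4)}
    n_multi_generation = 0

    for icsr in icsrs:
        gens = icsr.generations
        if len(gens) > 1:
            n_multi_generation += 1
        if attribution == "per_suspect":
            for suspect in icsr.suspects:
                name = suspect.drug.name
                drug_counts.setdefault(name, {s: 0 for s in SocCategory})
                for event in icsr.events:
                    drug_counts[name][event.soc] += 1
                    gen_counts[suspect.drug.generation][event.soc] += 1
        else:
            for gen in gens:
                for event in icsr.events:
                    gen_counts[gen][event.soc] += 1
            first_per_gen: dict[int, str] = {}
            for suspect in icsr.suspects:
                first_per_gen.setdefault(suspect.drug.generation, suspect.drug.name)
            for name in first_per_gen.values():
                drug_counts.setdefault(name, {s: 0 for s in SocCategory})
                for event in icsr.events:
                    drug_counts[name][event.soc] += 1

    if n_multi_generation:
        logger.warning(
            "%d reports list quinolones of more than one generation; "
            "events attributed to each generation", n_multi_generation,
        )

    def _row(group: str, lvl: str, counts: dict[SocCategory, int]) -> dict:
        rec = {"group": group, "level": lvl}
        rec.update({_SOC_COLUMNS[s]: counts[s] for s in SocCategory})
        rec["total"] = sum(counts.values())
        return rec

    rows: list[dict] = []
    grand = {s: 0 for s in SocCategory}
    for gen in (1, 2, 3, 4):
        rows.append(_row(f"gen{gen}", "generation", gen_counts[gen]))
        for s in SocCategory:
            grand[s] += gen_counts[gen][s]
        if level == "drug":
            members = sorted(
                n for n in drug_counts if QUINOLONE_CATALOG[n].generation == gen
            )
            rows.extend(_row(name, "drug", drug_counts[name]) for name in members)
    rows.append(_row("total", "total", grand))

    table = CountTable(pd.DataFrame(rows, columns=_COUNT_COLUMNS))
    table.validate(check_hierarchy=(attribution == "per_suspect"))
    return table
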
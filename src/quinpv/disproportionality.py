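"""Reporting odds ratio (ROR) signal detection on 2x2 contingency tables.

For an index drug group and a reference group, the 2x2 table is

                 target-SOC ADRs   other ADRs
    index group        a               b
    reference          c               d

with non-cases defined as all ADRs of the group outside the target SOC
(so the other two target SOCs count as non-cases).  The ROR is the
cross-product ratio ad/(bc); its 95% confidence interval is the Wald
interval exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); independence is
tested with the Pearson chi-square statistic on one degree of freedom,
without continuity correction.  A table containing a zero cell receives
the Haldane-Anscombe +0.5 correction (ROR and CI only) and is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .icsr import CountTable, SocCategory, TARGET_SOCS

__all__ = [
    "ContingencyTable",
    "DisproportionalityResult",
    "build_contingency",
    "ror_point",
    "wald_ci",
    "chi_square",
    "evaluate_pair",
    "compare_generations",
    "results_to_frame",
    "round_half_away",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a (index, target SOC), b (index, other), c (reference, target),
    d (reference, other)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class DisproportionalityResult:
    """One row of the pairwise comparison matrix, with full provenance."""

    index_group: str
    reference_group: str
    soc: SocCategory
    ror: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    zero_cell_corrected: bool
    table: ContingencyTable


def build_contingency(
    counts: CountTable,
    index_group: str,
    ref_group: str,
    soc: SocCategory,
) -> ContingencyTable:
    """Build the 2x2 for one (index group, reference group, target SOC)."""
    if soc not in TARGET_SOCS:
        raise ValueError(f"{soc} is not a signal-target SOC")
    if index_group == ref_group:
        raise ValueError("index and reference group must differ")
    a = counts.count(index_group, soc)
    b = counts.total(index_group) - a
    c = counts.count(ref_group, soc)
    d = counts.total(ref_group) - c
    return ContingencyTable(a, b, c, d)


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Haldane-Anscombe +0.5 on every cell when any cell is zero."""
    if (t.a + t.b) == 0 or (t.c + t.d) == 0:
        raise ValueError("empty group: cannot estimate reporting odds")
    if t.has_zero_cell:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def ror_point(t: ContingencyTable) -> float:
    """Reporting odds ratio ad/(bc) (on corrected cells if a cell is zero)."""
    a, b, c, d, _ = _corrected_cells(t)
    return (a * d) / (b * c)


def wald_ci(t: ContingencyTable, confidence: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the ROR on the log scale."""
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0,1), got {confidence}")
    a, b, c, d, _ = _corrected_cells(t)
    z = stats.norm.ppf((1 + confidence) / 2)
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def chi_square(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the raw table.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        raise ValueError("chi-square undefined: zero margin")
    chi2 = t.n * (a * d - b * c) ** 2 / math.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(p, 0.0)


def evaluate_pair(
    counts: CountTable,
    index_group: str,
    ref_group: str,
    soc: SocCategory,
    confidence: float = 0.95,
    *,
    zero_cell_policy: str = "haldane",
) -> DisproportionalityResult:
    """Full signal evaluation of one comparison."""
    t = build_contingency(counts, index_group, ref_group, soc)
    if t.has_zero_cell and zero_cell_policy == "error":
        raise ValueError(f"zero cell in {index_group} vs {ref_group} ({soc.value})")
    a, b, c, d, corrected = _corrected_cells(t)
    ror = (a * d) / (b * c)
    lo, hi = wald_ci(t, confidence)
    chi2, p = chi_square(t)
    return DisproportionalityResult(
        index_group=index_group,
        reference_group=ref_group,
        soc=soc,
        ror=ror,
        ci_low=lo,
        ci_high=hi,
        chi2=chi2,
        p_value=p,
        zero_cell_corrected=corrected,
        table=t,
    )


def compare_generations(
    counts: CountTable,
    socs: Sequence[SocCategory] = TARGET_SOCS,
    ref_group: str = "gen2",
    confidence: float = 0.95,
    *,
    index_groups: Optional[Sequence[str]] = None,
    zero_cell_policy: str = "haldane",
) -> list[DisproportionalityResult]:
    """One result per (non-reference generation, target SOC), against a
    fixed reference generation."""
    if index_groups is None:
        index_groups = [g for g in counts.groups("generation") if g != ref_group]
    results = []
    for soc in socs:
        for group in index_groups:
            results.append(
                evaluate_pair(
                    counts, group, ref_group, soc, confidence,
                    zero_cell_policy=zero_cell_policy,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Rendering


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for RORs and CIs)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, threshold: float = 0.001) -> str:
    return f"<{threshold:g}" if p < threshold else f"{p:.3f}"


def results_to_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    """Tabulate results (one row per comparison, internal full precision)."""
    return pd.DataFrame(
        {
            "index_group": r.index_group,
            "reference_group": r.reference_group,
            "soc": r.soc.value,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "chi2": r.chi2,
            "p_value": r.p_value,
            "zero_cell_corrected": r.zero_cell_corrected,
        }
        for r in results
    )
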
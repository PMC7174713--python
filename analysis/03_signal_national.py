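#!/usr/bin/env python
"""Disproportionality analysis of the published national count table.

Computes the full pairwise comparison matrix (reporting odds ratio, 95%
Wald CI, chi-square) of musculoskeletal, neurological and psychiatric ADR
reporting between quinolone generations, with the second and the third
generation each used as reference group."""

from pathlib import Path

from quinpv.disproportionality import (
    compare_generations,
    format_p,
    results_to_frame,
    round_half_away,
)
from quinpv.icsr import load_table1_counts

OUT = Path(__file__).resolve().parents[1] / "results" / "national"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = load_table1_counts()
    for ref in ("gen2", "gen3"):
        results = compare_generations(counts, ref_group=ref)
        frame = results_to_frame(results)
        out = OUT / f"signal_ref_{ref}.tsv"
        frame.to_csv(out, sep="\t", index=False, lineterminator="\n")
        print(f"reference {ref}: {len(results)} comparisons -> {out}")
    headline = [r for r in compare_generations(counts, ref_group="gen2")
                if r.index_group == "gen3"]
    for r in headline:
        print(f"  gen3 vs gen2, {r.soc.value:16s} "
              f"ROR {round_half_away(r.ror, 2):4.2f} "
              f"({round_half_away(r.ci_low, 2):4.2f}-{round_half_away(r.ci_high, 2):4.2f}), "
              f"p {format_p(r.p_value)}")


if __name__ == "__main__":
    main()
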
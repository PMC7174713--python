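#!/usr/bin/env python
"""Descriptive report of the synthetic listing: demographics blocks,
preferred-term frequency tables, SOC shares and time-to-onset summaries
(with a boxplot)."""

from pathlib import Path

from quinpv.descriptives import pt_frequency, summarize_cases, tte_distribution
from quinpv.icsr import TARGET_SOCS, read_line_listing

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    listing = ROOT / "synthetic" / "listing.csv"
    if not listing.exists():
        raise SystemExit(f"{listing} not found - run analysis/01_simulate.py first")
    icsrs = read_line_listing(str(listing))
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)

    summary = summarize_cases(icsrs)
    for name, block in summary.blocks.items():
        block.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False,
                     lineterminator="\n")
    if summary.age:
        print(f"age: median {summary.age['median']:.0f} "
              f"(IQR {summary.age['q1']:.0f}-{summary.age['q3']:.0f}), "
              f"n={summary.age['n']}")

    for soc in TARGET_SOCS:
        table = pt_frequency(icsrs, soc)
        table.to_csv(out / f"pt_frequency_{soc.value}.tsv", sep="\t",
                     index=False, lineterminator="\n")
        top = table.iloc[0]
        print(f"most reported {soc.value} term: {top['preferred_term']} "
              f"({top['count']}, {top['percent']}%)")

    tte = tte_distribution(icsrs)
    tte.to_csv(out / "time_to_event.tsv", sep="\t", index=False,
               lineterminator="\n")
    print("time to onset (days), median per SOC group:")
    for _, row in tte.iterrows():
        print(f"  {row['soc_group']:16s} {row['median']:.1f} "
              f"(IQR {row['q1']:.1f}-{row['q3']:.1f}, n={int(row['n'])})")

    from quinpv.cli import _tte_boxplot
    _tte_boxplot(icsrs, out / "time_to_event.svg")
    print(f"boxplot written to {out/'time_to_event.svg'}")


if __name__ == "__main__":
    main()
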
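#!/usr/bin/env python
"""Aggregate the synthetic line listing into drug/generation x SOC ADR
counts (the input shape of the disproportionality stage)."""

from pathlib import Path

from quinpv.descriptives import adrs_per_icsr, soc_share
from quinpv.icsr import aggregate_counts, read_line_listing

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    listing = ROOT / "synthetic" / "listing.csv"
    if not listing.exists():
        raise SystemExit(f"{listing} not found - run analysis/01_simulate.py first")
    icsrs = read_line_listing(str(listing))
    counts = aggregate_counts(icsrs, level="drug")
    out = ROOT / "synthetic" / "counts.tsv"
    counts.to_tsv(str(out))
    print(f"{counts.total('total')} ADRs (drug-event pairs) from {len(icsrs)} reports "
          f"-> {adrs_per_icsr(counts.total('total'), len(icsrs))} per report; wrote {out}")
    shares = soc_share(counts).set_index("soc")
    print("share of ADRs in the three target SOCs: "
          f"{shares.loc['target_socs_combined', 'percent_of_all']}%")


if __name__ == "__main__":
    main()
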
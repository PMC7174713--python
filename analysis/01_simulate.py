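#!/usr/bin/env python
"""Generate the synthetic ICSR line listing used by the downstream steps.

The national and regional report databases are not publicly available, so
the whole pipeline runs on a simulated reporting system whose per-generation
reporting-odds structure is calibrated to the published national count
table (the ground truth is written next to the listing)."""

from pathlib import Path

from quinpv.icsr import write_line_listing
from quinpv.simulate import default_config, generate, write_ground_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(n_icsrs: int = 5000, seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(n_icsrs=n_icsrs, seed=seed)
    icsrs, _ = generate(cfg)
    write_line_listing(icsrs, str(OUT / "listing.csv"))
    write_ground_truth(cfg, str(OUT / "truth.json"))
    n_events = sum(len(r.events) for r in icsrs)
    print(f"wrote {len(icsrs)} reports ({n_events} adverse events, "
          f"{n_events / len(icsrs):.1f} per report) to {OUT/'listing.csv'}")
    print(f"ground-truth reporting odds written to {OUT/'truth.json'}")


if __name__ == "__main__":
    main()
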
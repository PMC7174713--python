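#!/usr/bin/env python
"""Case-level evaluation of the synthetic listing: Naranjo causality,
risk-factor screening against the simulator's approved-indication pool,
and time to onset."""

from pathlib import Path

from quinpv.cases import evaluate_cases, risk_factor_crosstab
from quinpv.icsr import read_line_listing
from quinpv.simulate import APPROVED_INDICATION_POOL

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    listing = ROOT / "synthetic" / "listing.csv"
    if not listing.exists():
        raise SystemExit(f"{listing} not found - run analysis/01_simulate.py first")
    icsrs = read_line_listing(str(listing))
    approved = frozenset(APPROVED_INDICATION_POOL)
    out = ROOT / "cases"
    out.mkdir(parents=True, exist_ok=True)
    evaluation = evaluate_cases(icsrs, approved)
    evaluation.to_csv(out / "case_evaluation.tsv", sep="\t", index=False,
                      lineterminator="\n")
    crosstab = risk_factor_crosstab(icsrs, approved)
    crosstab.to_csv(out / "risk_factor_crosstab.tsv", sep="\t", index=False,
                    lineterminator="\n")
    target = evaluation[evaluation["soc_group"] != "none"]
    flagged = (target["n_risk_factors"] > 0).sum()
    print(f"{len(target)} of {len(icsrs)} reports involve a target SOC; "
          f"{flagged} of those ({100 * flagged / len(target):.1f}%) carry at "
          "least one risk factor")
    print(evaluation["causality"].value_counts().to_string())


if __name__ == "__main__":
    main()
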
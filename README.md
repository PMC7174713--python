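# quinpv

Disproportionality signal detection and case-level evaluation for
quinolone-induced musculoskeletal, neurological and psychiatric adverse
drug reactions (ADRs) reported to a spontaneous reporting system.

Quinolone antibiotics have come under regulatory restriction because of
serious, sometimes persistent reactions affecting muscles, joints and the
nervous system. This package implements the full analysis pipeline for
that question on Individual Case Safety Report (ICSR) data: it is aimed at
pharmacovigilance analysts who want a tested, reproducible implementation
of the reporting-odds-ratio comparison between quinolone generations, the
accompanying case-by-case assessments, and a simulator to exercise all of
it when the underlying reporting data cannot be shared.

## What it computes

**Signal detection.** ADRs are counted as (suspected quinolone, adverse
event) pairs and grouped by drug generation (1–4) and by System Organ
Class: *Nervous system disorders*, *Musculoskeletal and connective tissue
disorders*, *Psychiatric disorders*, or other. For an index generation
versus a reference generation and one target SOC, the 2×2 table

|            | target-SOC ADRs | other ADRs |
|------------|-----------------|------------|
| index      | a               | b          |
| reference  | c               | d          |

gives the reporting odds ratio ROR = ad/(bc), its Wald 95% CI
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) with z = 1.959964, and the Pearson
chi-square test (1 df, no continuity correction). Zero cells receive the
Haldane–Anscombe +0.5 correction and are flagged.

**Case evaluation.** Per-report Naranjo causality scoring (10 weighted
questions; doubtful ≤ 0, possible 1–4, probable 5–8, definite ≥ 9),
screening against six risk factors (age > 60 years, renal failure, organ
transplantation, corticosteroid use, history of side effects to
quinolones, non-approved therapeutic indication), and time to onset in
days from therapy start.

**Descriptives.** Demographics and categorical distributions,
preferred-term frequency tables per SOC, SOC shares, ADRs-per-report
ratio, and per-SOC-group five-number latency summaries.

**Simulation.** A seeded generator of synthetic ICSR line listings whose
per-generation SOC reporting odds are configured exactly (the configured
odds multipliers are the estimand of the ROR engine), used for oracle
tests, parameter-recovery and CI-coverage studies.

## Worked example

The package ships a transcription of the national drug × SOC ADR count
table (21,941 ADRs from 12,059 reports, 2002–2019). Comparing the third
generation (levofloxacin, moxifloxacin, pefloxacin) against the second
(ciprofloxacin and relatives):

```python
>>> from quinpv import load_table1_counts, build_contingency, SocCategory
>>> from quinpv.disproportionality import ror_point, wald_ci
>>> counts = load_table1_counts()
>>> t = build_contingency(counts, "gen3", "gen2", SocCategory.MUSCULOSKELETAL)
>>> (t.a, t.b, t.c, t.d)
(1094, 11664, 514, 7774)
>>> round(ror_point(t), 2), tuple(round(x, 2) for x in wald_ci(t))
(1.42, (1.27, 1.58))
```

Third-generation quinolones show 1.42 times the odds of a musculoskeletal
ADR relative to all their other ADRs, compared with second-generation
quinolones — a disproportionality signal (the CI excludes 1), not an
incidence estimate.

The numbered scripts under `analysis/` run the whole pipeline and print
their findings; `analysis/03_signal_national.py` prints the headline rows:

```
gen3 vs gen2, nervous          ROR 1.23 (1.11-1.38), p <0.001
gen3 vs gen2, musculoskeletal  ROR 1.42 (1.27-1.58), p <0.001
gen3 vs gen2, psychiatric      ROR 1.82 (1.58-2.08), p <0.001
```

The same operations are available from the shell:

```sh
quinpv simulate --seed 7 --n 5000 --out listing.csv --truth truth.json
quinpv aggregate --in listing.csv --out counts.tsv
quinpv signal --counts counts.tsv --ref-group gen2 --out results.tsv
quinpv cases --in listing.csv --out cases/
quinpv report --in listing.csv --out report/
quinpv all --seed 7 --n 5000 --out run/     # everything + hashed manifest
```

## Layout

- `src/quinpv/` — library: `icsr` (domain model, line-listing I/O,
  PT→SOC dictionary, aggregation), `disproportionality`, `cases`,
  `descriptives`, `simulate`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `scripts/acceptance.py` — recomputation of the headline numbers.
- `tests/` — pytest suite (unit, property and end-to-end tests).
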
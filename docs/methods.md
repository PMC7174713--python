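# Methods

## Analysis model

The pipeline treats a spontaneous reporting system as a collection of
Individual Case Safety Reports (ICSRs), each carrying one or more
suspected quinolones and one or more adverse events coded by preferred
term (PT). Events are mapped to a four-way System Organ Class (SOC)
grouping — nervous, musculoskeletal, psychiatric, other — through a
packaged PT→SOC mini-dictionary; matching is case-insensitive with
internal whitespace collapsed and deliberately performs **no fuzzy
matching** (a silent near-match would corrupt counts); unlisted terms fall
into the "other" class with a logged warning.

### Counting unit

The unit of analysis for signal detection is the **ADR**, i.e. the
(suspected quinolone, adverse event) pair: each event of a report
contributes one count for every suspected quinolone in that report. This
is the convention under which the packaged national count table's
per-drug counts and grand total are internally consistent, and under
which its published pairwise comparisons reproduce exactly. Counting once
per report (`attribution="per_report"`) is available but not the default;
reports listing quinolones of more than one generation are attributed to
each generation and flagged in the log.

### Disproportionality statistics

For an index group and a reference group, non-cases are **all ADRs of the
group outside the target SOC** — the other two target SOCs count as
non-cases. (The alternative, using only the "other SOCs" column, does not
reproduce the published comparison matrix; this definition does, exactly.)

* ROR = ad/(bc).
* 95% CI: Wald interval on the log scale, z = Φ⁻¹(0.975) = 1.959964
  (computed from the normal quantile at run time, not hard-coded to 1.96;
  invisible at two decimals but documented).
* Chi-square: Pearson statistic n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on the
  *uncorrected* table, 1 df, **no continuity correction** — the variant
  that reproduces the published p-values (e.g. 0.097 for first vs second
  generation, musculoskeletal).
* Zero cells: Haldane–Anscombe +0.5 on all four cells for the ROR and CI
  only, flagged in the result; the chi-square always uses raw cells.
  The generation-level national table contains no zero cells, so this
  path matters only for sparse user data.
* No multiple-testing adjustment by default, matching the source
  analysis.

Display rounding is half-away-from-zero at two decimals; internal values
are never rounded. P-values below 0.001 render as "<0.001"; below 1e-16
they are reported as 0 internally.

### Known print discrepancies in the reference analysis

Three published point estimates (1.83 neurological gen1 vs gen2, 1.81
psychiatric gen3 vs gen2, 0.47 musculoskeletal gen1 vs gen3) sit one
final-digit unit below recomputation (1.84, 1.82, 0.48) while their
printed intervals match exactly; two psychiatric CI lower bounds (0.44,
0.36, both against reference generation 3) likewise disagree with
recomputation (0.48, 0.37). The tests treat those cells accordingly
(point estimates within one final-digit unit; the two inconsistent
intervals checked on the point estimate only). The published count table
also prints a second-generation row (8,288 ADRs) that does not equal the
sum of its drug rows (8,388); the generation row is the one consistent
with the grand total and the comparison matrix, so the transcription is
kept verbatim and the drug-row hierarchy invariant is enforced only for
tables the package aggregates itself.

## Case evaluation

* **Naranjo scale**: the standard 10-question yes/no/unknown weights
  (+1, +2/−1, +1, +2/−1, −1/+2, −1/+1, +1, +1, +1, +1 for yes/no;
  unknown always 0), score range −4…13; categories doubtful ≤ 0,
  possible 1–4, probable 5–8, definite ≥ 9 ("definite" is the scale's
  "certain"; "Doubt" in some renderings is a display alias of doubtful).
* **Risk factors**: age strictly greater than 60 years (missing age never
  sets the flag), renal failure and organ transplantation from comorbidity
  flags, concomitant corticosteroid use, history of previous side effects
  *to quinolones* specifically, and therapeutic indication. The indication
  screen compares the recorded indication — normalized to lowercase with
  whitespace collapsed — against a user-supplied approved list; a missing
  indication is never flagged. The package ships the ten-item non-approved
  indication list of the reference case series for documentation and
  simulation; the approved list defaults to empty because no authoritative
  enumeration exists, so users must supply their own.
* **Time to onset**: onset date minus therapy start date in whole days;
  0 means same-day onset; negative latencies are validation errors and the
  affected report is excluded from latency summaries with a warning. When
  a report has several target-SOC events, its latency is the earliest
  onset among them minus the earliest therapy start (the reference
  analysis is silent on this; one rule is fixed and documented).
* Report-level SOC grouping: a report is classified by the single target
  SOC its events touch, "multiple" when ≥ 2 distinct target SOCs are
  represented, "none" otherwise.

## Descriptives

Percentages display half-away-from-zero at one decimal and each block
sums to 100 within rounding slack; missing categorical values form an
explicit "not_available" level. Quartiles (age, latency) use linear
interpolation between order statistics — the default of mainstream
numeric stacks — because IQR displays depend on the convention and none
is stated in the reference analysis. Age bins for national-style
tabulation close the ambiguous 65–66 gap at 66 while keeping the
conventional labels.

## Synthetic data generator

The generator stands in for the non-public reporting databases. Defaults
are the study conditions:

| parameter | default | origin |
|---|---|---|
| drug mix | national reporting frequencies (levofloxacin 49.3%, ciprofloxacin 37.3%, …) | national tabulation |
| baseline SOC probabilities | second-generation SOC shares (nervous 0.0644, musculoskeletal 0.0620, psychiatric 0.0350) | national count table |
| per-generation odds multipliers θ(g, SOC) | empirical odds ratios of the national table vs generation 2 | national count table |
| events per report | zero-truncated Poisson, mean 1.8 (rate found by root-solving mean(rate) = 1.8) | reported ADRs-per-ICSR ratio |
| latency (days) | geometric on {0,1,…} with means 1 / 3 / 3 / 2 for nervous / musculoskeletal / psychiatric / other | loose match to reported medians 0 / 2.5 / 3; the "other" mean is a package choice |
| age | normal(54, 25) truncated to [0, 100], 8.3% missing | reported median ≈ 55, IQR ≈ 36–70, missingness 8.3% |
| gender | 51% female / 41% male / 8% unknown | national tabulation |
| seriousness, outcome, reporter | regional distribution (65.4% not serious, …) | regional tabulation |
| risk-factor prevalences | renal failure 3.4%, transplantation 2.3%, corticosteroid 2.3%, prior reaction 1.1%, off-label indication 11.5% | regional case series |
| study window | 2002-01-01 … 2019-03-31 | national retrieval window |

**Odds construction.** Per generation g, each target SOC s receives
probability q = t/(1+t) with t = θ(g,s) · o₀(s), where o₀(s) is the
baseline odds of s versus everything else; the "other" class absorbs the
remainder. This keeps the odds of *every* target SOC versus all else at
exactly θ·o₀ simultaneously, so `ground_truth_ror(i, j, s) = θᵢ/θⱼ` is
exactly the estimand of the ROR engine — a renormalization of a single
adjusted category cannot achieve this for several SOCs at once.

**Randomness.** One numpy PCG64 stream seeded from the config drives all
draws in a fixed order (drug, event counts, SOC indices, then per-report
attributes), giving byte-identical line listings for equal seeds across
runs and platforms. Zero-truncated Poisson and truncated normal draws use
rejection resampling. Within a report, a colliding (PT, onset) draw is
re-drawn so no report lists the same term twice for the same day.
`simulate_generation_counts` draws only the generation × SOC event counts
— the sufficient statistic for the disproportionality stage — from the
same sampling distribution, and is used for replicate studies where
materializing full reports would be waste.

**What it does not emulate.** Reporting delays and secular trends,
duplicate or follow-up reports, regional clustering, correlated
risk-factor/age/SOC structure, drug–drug differences within a generation
beyond the drug mix, and free-text narratives. Naranjo answers are drawn
from three fixed templates reproducing the observed causality mix
(≈59% possible / 40% probable / 1% doubtful), not from a causal model.
Passing recovery tests on these data therefore demonstrates correctness
of the estimator and its interval under the assumed counting model — not
robustness to the messiness of real reporting data.

## Problem sizes used by the test suite

* Oracle equivalence: 100 random line listings of 20–200 reports; ROR via
  aggregation equals brute-force record enumeration exactly (integer
  arithmetic both ways).
* Parameter recovery and CI coverage: θ(gen 3, musculoskeletal) = 2.0,
  5,000 reports per replicate, 2,000 replicates; median ROR within 5% of
  2.0 and Wald coverage within [93%, 97%]. Two thousand replicates pin
  the coverage estimate to about ±0.5 percentage points; the measured
  coverage is ≈ 95%.
* Convergence: empirical odds ratio within 10% of θ = 2 at 50,000
  reports; mean events per report within 5% of 1.8 at 20,000.
* Property tests (hypothesis, derandomized): ROR antisymmetry and CI
  reciprocity, chi-square symmetry and agreement with an independent
  implementation, Naranjo score-equals-weight-sum over random answer
  vectors, aggregation conservation.

## Limitations

Disproportionality on spontaneous reports yields reporting signals, not
incidence or relative risk; under-reporting, notoriety effects and
channeling are untouched by the statistics here. The packaged PT→SOC
dictionary covers the preferred terms of the reference case series plus a
few spelling variants, not a full terminology; anything outside it is
"other". The Wald interval is asymptotic — with very sparse cells its
coverage degrades, which is why zero-cell tables are corrected and
flagged rather than silently estimated.
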
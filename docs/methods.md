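# Methods

## The analysis in one paragraph

VAERS is a passive surveillance registry: anyone may file a report, there is
no denominator of doses administered, and reporting propensity decays with
time since vaccination. The analysis implemented here therefore works
entirely within the registry: for each adverse-event category (Kawasaki
disease, the MIS family, Henoch–Schönlein purpura, vasculitis) it computes a
*normalized frequency* — flagged cases per 100,000 reports-with-symptoms in
a stratum — and asks whether those frequencies are compatible with a single
background incidence shared across vaccines. Incompatibility (wildly
different per-vaccine frequencies, formalized by per-stratum goodness-of-fit
tests and a cross-vaccine homogeneity test) is evidence against the
background-only reading of the data, not evidence of causation.

## Ingestion and joining

The three per-year files are joined on `VAERS_ID`, anchored on the report
(`VAERSDATA`) file: symptom terms are pooled over continuation rows
(`SYMPTOM1..5`, several physical rows per report when more than five terms
were coded) and de-duplicated; vaccine codes are de-duplicated per report.
Choices a maintainer should know:

* **Encoding** — cp1252 first, UTF-8 fallback: real VAERS exports are
  Windows-encoded.
* **Missingness is preserved** — unparseable or empty `AGE_YRS`/`NUMDAYS`
  cells become missing, never zero; ages outside [0, 120] years and negative
  onset intervals are treated as data-entry errors and recorded as missing
  with a warning.
* **Duplicates** — a `VAERS_ID` repeated within a file keeps its first row;
  an id repeated across year files keeps the first year. Both are logged.
  The registry's own guidance does not resolve either case; first-wins is
  deterministic and auditable.
* **Orphans** — symptom/vax rows with no matching data record are counted
  and logged, and excluded from analysis.
* A report with zero symptom rows is retained but excluded from every
  "reports with symptoms" denominator.

## Case extraction

Default policy is **exact, case-insensitive** matching of MedDRA preferred
terms (after trimming and whitespace collapsing). The alternative —
substring matching — would count distinct preferred terms such as
"Cutaneous vasculitis" or "Retinal vasculitis" as "Vasculitis" cases and is
retained only as an explicit sensitivity switch. The six default categories
are the searchable preferred terms for HS, KD ("Kawasaki's disease", the
registry's apostrophized spelling), MIS, MIS-A, MIS-C and vasculitis, plus
the composite "KD, MIS, MIS-A, or MIS-C" (union of members, computed after
atomic flags). A report is one case per category no matter how many of its
terms match.

## Tabulation conventions

Normalized frequency is `100000 · C / N` reduced to a printed integer. Two
conventions are implemented because the published tables demonstrably use
both: the per-vaccine table matches **round-half-away-from-zero** and the
per-age table matches **truncation**. Both are explicit parameters; the
defaults per table reproduce the published integers. A zero-case stratum is
printed as the upper bound `"<X"` with `X = floor(100000 / N)` — the
frequency a single case would not have exceeded.

One published quirk is reproduced deliberately: the per-vaccine table's
denominator counts reports at ages 0–5 while its case column counts flagged
reports at any age. The two age windows are therefore *independent
parameters* of `vaccine_frequency_table` (defaults: denominator 0–5,
numerator unrestricted, which reproduces the printed rows). Analysts should
be aware the resulting "frequency" mixes an all-ages numerator with a
child-age denominator; with both windows set equal the function computes the
conventional rate.

Other conventions: ages bin as `floor(AGE_YRS)` with an `N.A.` row for
missing; onset days print as `Blank` plus days 0–30 by default, with
beyond-horizon onsets excluded from the printed rows and logged; a report
listing k vaccine codes contributes to all k rows (no fractional
attribution).

One arithmetic audit finding: the published per-age table's age-29 cell
(1 case / 14,700) prints 7 where truncation gives 6 (6.80; 7 is the
half-rounded value), while every other cell follows truncation — e.g. age
21 (22.95 → 22) and age 23 (9.72 → 9). The audit reports this single cell
as a note rather than a failure, and the age-band summaries below use the
printed integers as published.

## Inference

* **Per-stratum test** — two-cell Pearson goodness-of-fit of (cases,
  non-cases) against expectations under the background proportion
  p₀ = rate/100,000, df = 1, upper-tail p. No continuity correction by
  default (switchable); an exact binomial alternative is provided for small
  expected counts, and any expected cell < 1 sets a warning flag on the
  result rather than failing.
* **Background rate** — default 20 per 100,000 (literature Kawasaki-disease
  incidence; 9 as sensitivity value). The literature rate is per year while
  registry frequencies are per report; the default comparison treats the
  rate as per-report — the only dimensionally direct reading — with an
  explicit `year_scale` multiplier exposed for sensitivity analyses.
* **Multiplicity** — Bonferroni α/m, with m the number of tested rows. On
  the published 30-row per-vaccine table this gives the 30-test family and
  the corrected threshold 0.05/30 ≈ 0.00167. Re-analysing that table at
  background 20/100k finds all 30 rows significant (minimum significant
  frequency 51); the unknown-vaccine stratum (UNK) can be excluded via a
  parameter, giving a 29-test family.
* **Band summaries** — mean and sample SD (n−1) of per-age frequencies over
  an age band. Zero-case ages either drop out (`exclude`) or contribute the
  integer of their `"<X"` bound (`use_bound`); the latter is what reproduces
  the published adult-band summary (ages 18–30: mean 19.9, SD 15.1), and
  the child and teen bands reproduce as 391.5/204.9 (ages 1–13) and
  142.5/19.1 (ages 14–17).

## The reporting model

Expected reported events over an n-day collection horizon:

```
E_background = Σ_{age=0..100} P_age · Σ_{day=0..n} r_day · b_age
E_vaccine    = Σ_{age=0..100} P_age · Σ_{day=0..n} r_day · (v_age + b_age)
```

with `P_age` the population by single year of age (the age grid is fixed at
0..100), `r_day ∈ [0,1]` the reporting-bias decay, `b_age` the background
per-person per-day event probability, and `v_age` the additive
vaccine-attributable excess (zero under the no-association hypothesis). The
implementation is the vectorized factorization `Σr · Σ P(b+v)`; tests pin it
to a literal brute-force double loop at 10⁻¹² relative tolerance.

The model specifies expectations only. The simulator's distributional
choice is **Poisson per (age, day) cell** with mean `P·r·(v+b)` — the
standard rare-event approximation — with an exact Bernoulli-per-person
(binomial) mode for small populations. Seeding is a single integer with
deterministic stream splitting per stratum, so runs are bit-reproducible.

The **homogeneity test** (chi-squared independence on the K×2 cases versus
non-cases table, df = K−1, no continuity correction) operationalizes the
choice between the two hypotheses: under background-only reporting the
per-vaccine rates are exchangeable. `hypothesis_power_curve` simulates K
strata with one stratum's excess scaled along a grid and reports the
rejection rate per scale; the scale-0 entry estimates the type-I error.

Calibration at the conditions used throughout the tests (10 strata of 5,000
reports at background 20/100,000, α = 0.05): the measured type-I error is
≈ 0.04–0.05 — acceptable given expected counts of ≈ 1 per stratum — and
measured power against a single stratum at 10× background is ≈ 0.93–0.95.
The asymptotic (noncentral chi-squared, λ ≈ 38, df = 9) power at these
conditions is right at the 0.99 boundary, and the small expected counts pull
the finite-sample power below it; detecting a 10× signal with near-certain
power needs larger strata or a larger excess.

## The synthetic generator

`synthetic_data.generate` emits triplets in the exact ingestion dialect
under the vaccine-augmented model, with ground truth (per-report flags,
per-vaccine counts/denominators, generating parameters) in a JSON sidecar —
never inside the VAERS files, so the pipeline cannot read its own answers.
Defaults are the study conditions and stay fixed:

| parameter | default | rationale |
|---|---|---|
| background rate | 20 / 100,000 reports | the literature KD incidence used by the inference layer |
| onset decay ρ | 0.9 per day, horizon 30 d | geometric reporting decay; mass concentrated in week 1, matching the shape of published onset tables |
| P(missing age) | 0.10 | registry age fields are frequently blank |
| P(missing onset) | 0.25 | published onset tables carry large "Blank" rows, of the same order as day 0 |
| P(co-administration) | 0.30 | childhood schedules routinely give several vaccines per visit |
| P(no symptom rows) | 0.02 | a small share of reports code no symptom terms |
| symptom terms per report | 1 + Poisson(2) | occasionally exceeds 5, forcing continuation rows |

Case reports receive the category's exact preferred term; filler reports
draw decoys including superstrings of the searched terms. What the
generator does **not** emulate: free-text narratives, MedDRA coding errors
and spelling variants, duplicate or follow-up filings of one clinical
event, secular trends in reporting volume, and any correlation between age
and symptom count. Passing round-trip tests therefore demonstrates that the
pipeline's bookkeeping is exact on clean registry-shaped data, not that
extraction is robust to real-world coding noise.

`fixture_small` is a hand-written 12-report triplet covering the awkward
cases (multi-vaccine report, 7-term report with continuation rows, missing
age, missing onset, superstring decoy, UNK code, zero-symptom report) with
planted counts: 3 KD cases, 3 exact vasculitis cases (4 under substring
matching), 1 HS, 1 MIS-C.

## Numerical and testing notes

* Round-half-away is implemented as `floor(x + 0.5)` on non-negative x,
  immune to banker's rounding; truncation as `trunc`.
* Problem sizes in the test suite: round-trip and distributional checks use
  a 10,000-report cohort (5 strata × 2,000); Monte-Carlo calibrations use
  1,000 replicates (10,000 for simulator-mean agreement); the homogeneity
  power grid uses 100–500 replicates per scale. These sizes make the Monte
  Carlo error small relative to the tolerances asserted.
* Degenerate inputs: empty report lists yield empty tables; a zero
  denominator is a domain error for frequencies, drops the row (logged) in
  per-vaccine tables, and yields a missing frequency in per-age tables; an
  all-zero case column makes the homogeneity test return p = 1.

## Known limitations

* Normalized frequencies are reporting rates, not incidence: the
  denominator is reports, not doses or person-time, and all the registry's
  reporting biases pass through.
* The model's `r_day`, `b_age`, `v_age` are not identifiable from registry
  counts alone and are not estimated; the model is used as an expected-count
  calculator and simulator.
* Exact preferred-term matching misses spelling variants and narrow
  sub-terms; substring matching over-counts. Both ends of that trade-off
  are exposed, neither is "correct".
* The per-vaccine table's numerator/denominator age asymmetry (above) means
  its frequencies should be compared across vaccines, not interpreted as
  absolute child rates.
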
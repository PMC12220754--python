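# Methods

## Scope and model

`pvsignal` screens spontaneous adverse-event reports for disproportionate
(drug, event) reporting. The unit of analysis is the deduplicated case
report. For a target drug and event the universe of N reports is partitioned
into a 2×2 table: the "exposed" margin (a+b) contains exactly the reports
naming the drug with the primary-suspect (PS) role; reports naming it only
in a secondary role (SS/concomitant/interacting) are comparators by design,
because the screening question is defined by the PS query. Cells are report
counts: a report with k PTs contributes to k PT-level tables, but within one
SOC it counts once at SOC level (report-level counting keeps every table's
N equal to the universe size).

Disproportionality is *not* an incidence comparison: there is no denominator
of drug users, and reporting is biased (publicity, litigation, drug age).
The four-way intersection rule below is the only error control applied — no
multiple-testing adjustment is made, matching screening practice where the
flagged list feeds clinical review rather than formal inference.

## The four statistics

All four are computed exactly as printed in the classical sources, in
double precision, and are validated against an independent exact-rational
(sympy) evaluation to relative error < 1e-10 on random tables with cells in
[1, 10^4].

* **ROR** = ad/bc; 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Undefined if any cell is 0 (see *Degenerate tables*).
* **PRR** = [a/(a+b)]/[c/(c+d)]; CI uses SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d));
  χ² = (ad−bc)²N/((a+b)(a+c)(c+d)(b+d)), uncorrected. A Yates-style
  continuity correction is deliberately not applied by default; the χ²
  statistic is validated against `scipy.stats.chi2_contingency(correction=False)`.
  PRR is defined for a > 0, c > 0; b = 0 is fine (the 1/a − 1/(a+b) term
  vanishes).
* **BCPNN**: naive IC = log₂(aN/((a+b)(a+c))). Shrinkage uses the standard
  priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), which centres the prior IC at 0:

      E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
      V(IC) = (ln2)⁻² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                      + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                      + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]

  The signal bound is IC−2SD = E(IC) − 2√V(IC), with tiers none/weak/medium/
  strong at 0, 1.5, 3. E(IC) and V(IC) are finite for zero cells; as all
  cells scale up, E(IC) → IC and V(IC) → 0 (tested at k = 1, 10, 100, 1000).
* **EBGM** as implemented is the unshrunk relative reporting ratio
  aN/((a+c)(a+b)) with log-scale bounds exp(ln EBGM ± 1.96·√(1/a+1/b+1/c+1/d)).
  By construction EBGM = 2^IC exactly — the identity is asserted in tests.
  A genuine multi-item gamma-Poisson shrinker (EM fit of the mixture prior)
  would shrink small-count estimates toward 1 and is left as an explicit
  future backend; published EBGM columns produced by shrinkage software will
  therefore sit below the values this ratio gives.

**Criteria.** ROR: a ≥ 3 and CI lower bound > 1. PRR: additionally PRR ≥ 2
and χ² ≥ 4. BCPNN: IC−2SD > 0. EBGM: EBGM05 > 2. The overall verdict is the
conjunction of all four; by construction it is never more permissive than
any single criterion. Thresholds are a frozen dataclass and can be
overridden, but the defaults are the published ones.

### Degenerate tables

Zero cells leave ROR (any cell), the PRR CI (a or c), and the EBGM CI (any
cell) undefined; undefined statistics are reported as NaN with a `defined`
flag and automatically fail their criterion. A Haldane–Anscombe +0.5
correction is available behind a flag (default off): the a ≥ 3 case
criterion already excludes the tables where it would matter, and the
classical formulas are implemented as printed. BCPNN is the exception — its
priors regularize zero cells, and an a = 0 table yields a finite E(IC) with
IC−2SD ≤ 0 (never a signal).

## Cleaning rules

* **Deduplication** keeps, per case id, the highest case version; ties break
  by latest receipt date, then lexicographically largest primary id. This
  mirrors the FAERS convention that later case versions supersede earlier
  ones. Deduplication is idempotent and order-insensitive (output sorted by
  case id), never increases the record count, and preserves the case-id set.
  Cases with no reaction rows are dropped and counted — a spontaneous report
  must carry at least one event.
* **Ages** are binned as [0,18), [18,45), [45,65), [65,75), [75,∞); missing
  or implausible (<0 or >120) ages become "unspecified".
* **Drug names** are mapped case- and whitespace-insensitively through a
  verbatim→canonical dictionary; unmapped names pass through verbatim and
  are counted. The shipped dictionary is a small toy vocabulary.
* **PT→SOC**: each PT has one primary SOC. PTs absent from the map are
  routed to a sentinel `UNMAPPED` SOC rather than dropped, preserving every
  table's N. The shipped map is a synthetic toy vocabulary with invented
  codes — MedDRA is licensed and none of its content is included.
* Every dropped or rewritten row increments a named counter in a
  `CleaningLog`; the pipeline writes these alongside the stage counts.

## The synthetic generator

The generator exists so that every downstream stage has known ground truth.
Per report: each of the D vocabulary drugs is carried independently with
probability `drug_exposure_prob`; among carried drugs one is chosen
uniformly as PS, the rest get SS/C/I; each PT is an independent Bernoulli
with probability `baseline_event_prob`, multiplied by the relative rate of
any planted (drug, PT) signal when the report carries that drug (capped
at 1; multiple signals on one PT multiply). Demographics (sex, age bin with
a uniform age inside the bin, country, reporter, receipt year) are drawn
from categorical tables; serious-outcome codes are independent Bernoullis
because real reports carry several at once.

Two fill-in rules keep the record invariants without distorting any real
pair's 2×2: a report that draws zero events receives the designated
background PT ("Drug ineffective" by default — spontaneous reports always
list at least one reaction), and a report that draws zero drugs receives a
designated background drug in the concomitant role (never PS). If no
background PT is configured, a zero-event draw is an error.

Duplicates: `inject_duplicates` re-emits exactly ⌊rate·n⌋ seeded-selected
cases with version+1 and a later receipt date, flagging the superseded
originals — so deduplication can be tested against exact ground truth.

**Closed-form truth.** With PS assigned uniformly among carried drugs,
P(drug is PS) = (1−(1−p)^D)/D by symmetry, and the population cell
probabilities of the PS-universe 2×2 follow directly (implemented in
`expected_cell_probabilities`). The multiplier acts on *carriage* while the
table conditions on the *PS role*, so carried-but-not-PS reports dilute the
comparator arm: the attained odds ratio is below the multiplier.
`multiplier_for_target_odds_ratio` inverts the closed form numerically when
a specific true odds ratio is wanted. The closed form is verified in tests
against an independently coded Monte-Carlo re-simulation of the model.

**Default demographic mix.** The defaults reproduce the reference cohort
profile of 19,630 montelukast primary-suspect reports (2004–2023Q3): 53.01%
male, 31.01% under 18, 52.10% US, hospitalization 20.31%, consumer reporters
39.24%, peak year 2013 with 10.86% of reports (the non-peak years share the
remainder evenly — a simplification; real annual curves are multi-peaked).
`build_reference_cohort` materializes this profile exactly (categorical
fields assigned independently by slicing), which is what the descriptives
acceptance check summarizes.

**What the generator does not emulate** — and hence what passing tests do
not establish about real FAERS data: reporting delays and backlog, the
Weber and notoriety effects, correlated events within a report (events are
independent given exposures), drug–drug interaction signals, dose and
therapy dates, country- or year-varying drug usage, and free-text noise
beyond simple verbatim drug-name variants. Calibration results (null flag
rate, CI coverage) are statements about this generative model, not about
reporting-bias-contaminated real data.

## Quarterly file dialect

One `$`-delimited text file per table (DEMO, DRUG, REAC, OUTC), first row =
column names; DEMO carries primaryid/caseid/caseversion/fda_dt/sex/age/
occr_country/occp_cod, DRUG primaryid/drugname/role_cod, REAC primaryid/pt,
OUTC primaryid/outc_cod. There is no quoting or escaping: a field containing
`$` cannot be represented and the writer rejects it. The writer/reader pair
round-trips record sets losslessly (asserted in tests).

## Calibration conditions and problem sizes

The simulation checks use fixed study conditions: the null calibration runs
one universe of 100,000 reports, 10 drugs (exposure 0.15) and the 50-PT toy
vocabulary at baseline 0.02, screening all 500 (drug, PT) pairs — fewer than
1% may pass the four-way rule (observed: 0). The coverage calibration runs
200 replicates of 10,000 reports (5 drugs, exposure 0.3, baseline 0.02)
with the planted multiplier chosen so the true PS-universe odds ratio is 4;
the 95% ROR CI must cover the truth in 93–97% of replicates. At these cell
sizes (a ≈ 130) the Wald interval is close to nominal, but the band is only
±1.3 standard errors wide at 200 replicates, so occasional excursions just
outside it are expected behaviour of a correctly calibrated interval, not a
defect. These sizes keep the full suite and the acceptance script around a
minute each.

## Numerical choices

Percentages are computed on exact rationals and rounded half-up to 2
decimals (`Fraction`-based; float formatting also uses half-up), so printed
values are reproducible to the digit. Statistics use 1.96 (not the exact
normal quantile) because that is what the printed formulas state; the
statsmodels cross-check therefore agrees to ~1e-3, while the exact-rational
oracle (which also uses 1.96) agrees to <1e-10. Ranking ties break by case
count then event name; dedup ties as described above; all randomness flows
from a single integer seed through `numpy.random.default_rng`, and pipeline
outputs contain no timestamps, making reruns byte-identical.

## Known limitations

No stratified (age/sex/year) tables; no MedDRA versioning or SMQs; no true
EBGM shrinkage (see above); the IC credible bound is the normal-style
E(IC) − 2√V(IC) rather than an exact posterior quantile; the CLI does not
persist intermediate cleaned universes (clean/screen/summarize re-read the
quarter).
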
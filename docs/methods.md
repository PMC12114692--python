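# Methods

`pvsignal` implements a case/non-case (disproportionality) analysis of
spontaneous adverse-event reports, in the style used for EudraVigilance and
FAERS line listings, together with the descriptive statistics that usually
accompany such an analysis. This note records the statistical conventions,
the design choices made where several were defensible, and what the
synthetic data can and cannot show.

## Data model

One **ICSR** (individual case safety report) describes one patient and
carries: a local report number, receipt date, origin region (EEA, UK,
non-EEA), seriousness with its qualifying criteria, a fatal-outcome flag,
reporter qualification, sex, an EudraVigilance-style age band, the suspect
drug set, and an ordered list of MedDRA Preferred Terms (PTs). Invariants
are enforced at construction: at least one reaction, no repeated PT within a
report, and a fatal outcome implies a serious report with the death
criterion.

MedDRA is licence-encumbered, so the package never ships the dictionary;
the user supplies the slice needed as two-column CSVs: PT → System Organ
Class (SOC) and PT → canonical merged term. Merging must be idempotent and
every merge target must be SOC-mapped. Terms outside the slice pass through
unchanged and aggregate under an `Unmapped` bucket.

## Cohort construction

The standard serious-report cohort applies, in order: inclusion criteria
(serious, healthcare-professional reporter, EEA+UK origin, receipt date in a
window, drug of interest among the suspects), removal of incomplete reports,
duplicate removal, then synonym normalization. Filters are pure and commute;
the run manifest records the count after every stage.

**Duplicate rule.** Two reports are linked when they share a local report
number, or when sex, age band and suspect-drug set are identical and the
Jaccard similarity of their reaction sets reaches a threshold (default 1.0,
i.e. identical sets; configurable down to 0.5 — public line listings expose
no better linkage key, and probabilistic record linkage is out of scope).
Groups are the transitive closure of this relation. Within a group the
earliest-received report survives, ties broken by smallest report number.
Deduplication runs **before** synonym merging: merging first would manufacture
field-identical reports out of clinically distinct ones.

**SOC aggregation is case-level**: a report contributes at most one count to
a SOC no matter how many of its PTs map there. This is the convention that
makes per-SOC case counts and per-SOC "all other cases" sum to the cohort
size.

## Stratified tables and the chi-square variant

Per-PT tables split by sex or by two age strata (default 18–64 vs 65–85,
the cohort restricted to those strata). Row percentages are per-stratum
shares of the term's row total; the "% of all reports" column always uses
the full cohort as denominator, even when display rows are filtered by a
minimum count. Percentages are shown to one decimal, rounded half-up.

The association test on each 2×2 is the chi-squared test with Yates
continuity correction in its **non-floored** form:

    chi2 = sum over cells of (|O - E| - 0.5)^2 / E

with the corrected deviation squared as signed even when `|O − E| < 0.5`
(SPSS's 2×2 "continuity correction" output behaves this way, as does
`scipy.stats.chi2_contingency(correction=True)`, which adjusts observed
values toward expected by 0.5). The textbook variant that floors the
deviation at zero is available via `floored=True`; it never exceeds the
Pearson statistic, and the two coincide whenever all `|O − E| ≥ 0.5`. The
p-value is the upper tail of χ²(1), `erfc(sqrt(chi2/2))`. A term present in
only one stratum is reported as not applicable (no test); degenerate margins
return p = 1 with a warning.

Unknown-sex and unknown-age reports are excluded from test margins but kept
in the "% of all" denominators.

The fatal-outcome summary counts deaths whose reactions avoid an exclusion
set (default: completed suicide, so the summary isolates other causes),
with percentages against the full cohort and against each age stratum's
size.

## Disproportionality

For an event (PT or SOC) and two drug cohorts A and B the case/non-case
table is `a = |A with event|, b = |A| − a, c, d` likewise for B, and

    ROR = (a d) / (b c),   95% CI = exp(ln ROR ± z sqrt(1/a + 1/b + 1/c + 1/d))

with `z = 1.959964` (Woolf log-normal interval). A **signal** is a result
whose CI lower bound exceeds 1. The ROR is a reporting association measure,
not a causal risk estimate; no multiplicity adjustment is applied across an
event panel, matching field practice for hypothesis-generating screens.
Zero cells use Haldane–Anscombe correction (+0.5 to every cell, flagged
`corrected`) by default; policy `none` raises when the ratio is undefined.
Display rounding is half-up to two decimals; full precision is kept
internally.

## Synthetic cohorts

### Random generator

`generate_cohort` draws, per drug, each profile PT independently per case;
cases with no reaction at all are redrawn. Demographics, seriousness,
reporter, region, fatal outcome and receipt dates are independent draws with
configured rates. Everything is a pure function of the config, including its
seed. A configurable fraction of cases is copied into a near-duplicate row
differing only in receipt date, with ground-truth index pairs returned.

Two features depart from a literal independent-draw model, both because
spontaneous reports are never carbon copies:

* **Collision distinguishing** (default on): base cases that coincide by
  chance on sex, age band, drug and reaction set receive an extra
  "background" PT from a reserved vocabulary, so the duplicate rule links
  exactly the injected duplicates. Profiles may not use the reserved names
  while this is enabled.
* The all-empty **redraw conditions marginal rates upward** by a factor
  `1/(1 − P(empty))`. Tests of marginal frequencies and of interval coverage
  therefore use profiles whose `P(empty)` is negligible (e.g. a baseline
  reaction with probability near 1); `implied_odds_ratio` returns the odds
  ratio of the configured probabilities, which the redraw leaves untouched
  in that regime.

The generator models no within-case reaction correlation, no reporting
dynamics over calendar time, and no under-reporting; passing tests on these
cohorts demonstrate the pipeline's arithmetic and its frequentist
calibration under the stated model, not robustness to real-world reporting
biases.

### Reference study preset

`reference_study()` constructs, combinatorially and without randomness,
three fixed cohorts — esketamine (751 raw reports, 265 serious),
fluoxetine (1066 serious) and venlafaxine (2019 serious) — whose per-PT
counts, sex and age splits, SOC case counts, suicidality counts and death
breakdown equal a reference EudraVigilance serious-report extraction
(EEA + UK, 2019–2024). Counts are planned first (northwest-corner splits of
each PT's sex×age margins, then packing PT slots into per-cell record
budgets), records second; the construction re-runs the whole pipeline on
itself and raises naming the first conflicting margin, so the preset cannot
silently drift.

Free dimensions the reference tables do not pin down are filled
deterministically and deserve explicit mention:

* Joint sex×age cells per PT follow a northwest-corner rule (males assigned
  to the adult stratum first).
* The five serious reports outside the two analysed age strata carry an
  unknown age band.
* SOC targets not covered by the tabulated PTs are met by single-PT filler
  reports, each filler term capped at 4 occurrences so no display threshold
  is crossed.
* **Two tabulated PTs are deliberately unmapped.** The reference tables are
  mutually inconsistent at case level: 43 increased-blood-pressure cases and
  17 drug-ineffective cases cannot sit inside SOC totals of 18
  (Investigations) or 14 (General disorders). The preset's PT→SOC slice
  therefore leaves those two PTs in the `Unmapped` bucket and meets the SOC
  totals with mapped terms; diplopia maps to Eye disorders, a SOC outside
  the compared panel.
* The two psychiatric-SOC comparator "all other cases" margins in the
  reference tables (919, 1758) contradict the tabulated cohort totals
  (1066, 2019);
  a single consistent cohort necessarily yields 748 and 1446. The pipeline
  reproduces the printed case cells and cohort totals; the panel contrast
  built directly from the printed cells is computed as such where required.
* Identical stub reports are distinguished with background PTs exactly as
  in the random generator.

## Problem sizes and tolerances

All deterministic checks run on the preset cohorts (3 836 reports total) in
well under a second. The interval-coverage check uses 200 replicates per
configured odds ratio ω ∈ {1, 2, 5} with cohort sizes 300 and 2000 and a
band of 95% ± 3.5% (≈ 2.3 binomial standard errors at n = 200). Floating
comparisons against closed-form oracles use relative tolerance 1e−12;
printed-value comparisons use the printed precision (two decimals for
ROR/CI, six for p-values, one for percentages).

## Known limitations

* No E2B(R3) XML ingestion and no live database access; input is the
  delimited line-listing dialect (configurable delimiter/column map).
* Drug names are normalized by case-folding and trimming only; no
  brand↔INN dictionary.
* "Incomplete report" can only mean a missing suspect-drug set in this data
  model, since the record type cannot represent missing seriousness or an
  empty reaction list.
* The duplicate rule is field-similarity only; true duplicates with
  discrepant demographics escape it, as they do in the public line listings.
* PRR, EBGM/MGPS and Bayesian IC statistics are intentionally absent; the
  package computes the ROR family only.
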
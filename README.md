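# pvsignal

Signal detection on spontaneous adverse-event reports. `pvsignal` ingests
individual case safety report (ICSR) line listings of the kind exported
from EudraVigilance or FAERS, builds analysis cohorts (seriousness /
reporter / region / date filters, near-duplicate removal, MedDRA synonym
merging), aggregates Preferred Terms to System Organ Class level, produces
sex- and age-stratified descriptive tables with a continuity-corrected
chi-square test, and screens drug–event pairs for disproportionate
reporting with the reporting odds ratio (ROR).

It is aimed at pharmacovigilance analysts and methods researchers who work
from public line listings rather than live database queries, and at anyone
who needs a fully reproducible, testable version of this very common study
design.

## The statistics

For an event *E* and two drug cohorts A (study drug) and B (comparator),
with *a* = reports for A mentioning *E*, *b* = |A| − *a*, and *c*, *d*
likewise for B:

```
ROR = (a·d)/(b·c)        95% CI = exp( ln ROR ± z·√(1/a + 1/b + 1/c + 1/d) )
```

with z = 1.959964 (Woolf interval). A pair is flagged as a **signal** when
the CI lower bound exceeds 1. Counting is case-level throughout: a report
counts once per event (or per SOC) no matter how many of its PTs match.

Stratified tables use the Yates-corrected chi-square on the 2×2 table,
`Σ (|O−E|−0.5)²/E` with one degree of freedom, applying the correction as a
signed term even when |O−E| < 0.5 (the SPSS-style convention; the floored
textbook form is available via `floored=True`).

A seeded synthetic-data module generates random cohorts with known ground
truth (per-drug reaction probabilities, demographic mixtures, injected
near-duplicates) and also provides `reference_study()`, a deterministic
three-drug study — esketamine vs the antidepressants fluoxetine and
venlafaxine, serious EEA+UK reports, 2019–2024 — whose every table margin
matches a reference EudraVigilance extraction, so the whole pipeline can be
exercised end-to-end against known numbers. See `docs/methods.md` for the
conventions and their rationale.

## Worked example

```python
from pvsignal import (
    apply_cohort_criteria, find_duplicates, drop_duplicates,
    normalize_reactions, build_case_noncase, ror_with_ci,
    sex_distribution, reference_study, reference_criteria,
)

study = reference_study()          # deterministic reference cohorts
cohorts = {}
for drug, raw in study.raw_records.items():
    kept = apply_cohort_criteria(raw, reference_criteria(drug))
    kept = drop_duplicates(kept, find_duplicates(kept))
    cohorts[drug] = normalize_reactions(kept, study.meddra)

table = build_case_noncase(
    cohorts["esketamine"], cohorts["fluoxetine"], "Suicidal ideation", study.meddra
)
r = ror_with_ci(table, event_label="Suicidal ideation",
                drug_a="esketamine", drug_b="fluoxetine")
print(table.cells, r.ror_display, r.ci_display, r.signal)

row = sex_distribution(cohorts["esketamine"], "Completed suicide")
print(row.count_stratum1, row.count_stratum2, f"{row.p_value:.6f}")
```

prints

```
(26, 239, 38, 1028) 2.94 (1.75, 4.94) True
12 5 0.005334
```

Reading: 26 of the 265 serious esketamine reports mention suicidal
ideation against 38 of 1066 for fluoxetine; the reporting odds are
2.94-fold higher for esketamine and the interval excludes 1, so the pair is
flagged for assessment (a reporting signal, not a causal estimate).
Completed suicide splits 12 male / 5 female, a sex imbalance with
p ≈ 0.005 on the corrected chi-square.

The same analysis is available from a shell:

```
pvsignal synth --preset --out study/          # write the reference listings
pvsignal ror study/esketamine.csv study/fluoxetine.csv "Suicidal ideation" \
    --soc-map study/pt_to_soc.csv --synonyms study/synonyms.csv
pvsignal run config.yaml                      # full pipeline, tables + manifest
```

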
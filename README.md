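# formswitch

Switching outpatient medication lists onto a hospital formulary, the way a
hospital pharmacy does it at admission.

In most healthcare systems the outpatient and inpatient sectors are
separate: the ward may only dispense products on the hospital's formulary,
so every medication a patient brings to an elective admission must either
be found on that list or be mapped onto it. `formswitch` implements this
process end to end for clinical-pharmacy workflows and for studying such
workflows on synthetic cohorts:

1. **Medication reconciliation** — merge what the pharmacist interview,
   the brought-in medication list and the medical documents each know
   about a medication into one record, with per-field provenance,
   surfaced conflicts and completeness flags (unknown product name /
   unknown strength).
2. **Medication review** — pairwise drug–drug-interaction screening over
   all concomitant ingredients (combination products contribute each
   component) and potentially-inappropriate-medication screening for
   patients aged ≥ 65 (PRISCUS membership or FORTA grade C/D).
3. **Switching cascade S0–S5** — after gates for *not prescribed during
   the stay*, *self-medication*, *unknown product* and *unknown strength*,
   each eligible medication stops at the first matching step:

   | step | meaning | order channel |
   |------|---------|---------------|
   | S0 | exact product on the formulary — no switch needed | pharmacy stock |
   | S1 | ingredient on the substitution-exclusion list (carbamazepine, phenobarbital, phenytoin, primidone, valproic acid, ciclosporin, tacrolimus) — switching not allowed | special request |
   | S2 | *aut idem*: same ingredient, salt, strength and dosage-form class in another product (generic); combinations switch combo-for-combo or by all-or-nothing decomposition into mono-products, counted as one switch | pharmacy stock |
   | S3 | *aut simile*: an explicit dose-equivalence table entry (e.g. omeprazole 20 mg → pantoprazole 40 mg) maps to an equivalent formulary product, within the shared ATC level 4/5 group | pharmacy stock |
   | S4 | patient-individual switch — only via an explicit pharmacist override entry, never auto-derived | pharmacy stock |
   | S5 | nothing matched — the original product is ordered | wholesaler |

   Decisions aggregate into per-channel order lists.

The knowledge bases (formulary, exclusion list, equivalence tables,
interaction table, PIM catalogs) are plain CSV files validated against
shipped JSON schemas; a small default set is packaged. The `cohort_fixtures`
module additionally provides a deterministic 100-patient / 475-medication
study cohort whose *attribute flags* (not labels — the engine re-derives
every step) reproduce a published evaluation of this workflow, plus a
seeded random-cohort generator for property testing.

## Worked example

```python
from formswitch import (build_paper_fixture, decide_cohort,
                        review_report, summarize)

patients, kb, overrides = build_paper_fixture()
review = review_report(patients, kb)
decisions = decide_cohort(patients, kb, overrides)
summary = summarize(decisions, patients, review)

print(summary.status_counts)
print(summary.review["with_ddi"], "/", summary.review["assessable"],
      "patients with a drug-drug interaction")
print(summary.combinations)
```

prints

```
{'S0': 88, 'S1': 1, 'S2': 200, 'S3': 8, 'S4': 2, 'S5': 39,
 'NOT_PRESCRIBED': 15, 'SELF_MEDICATION': 0,
 'MISSING_PRODUCT': 114, 'MISSING_STRENGTH': 8}
31 / 79 patients with a drug-drug interaction
{'n': 23, 'mono': 13, 'mono_pct': 57.0,
 'combination': 9, 'combination_pct': 39.0, 'unresolved': 1}
```

Reading: of the 475 reconciled medications, 88 (18.5%) were already
stocked (S0), 200 (42.1%) could be switched generically (S2), 8 via
equivalence tables (S3), 2 by individual pharmacist decision (S4) and 39
(8.2%) had to be ordered from the wholesaler (S5); one carbamazepine
record was exclusion-listed (S1). 114 records could not enter the cascade
because the product name was unknown, 8 because the strength was unknown,
and 15 were not prescribed during the stay. Of the 23 combination
products, 13 (57%) resolved to mono-products and 9 (39%) stayed on a
combination product.

The same run is available from the shell:

```
formswitch fixtures export --out fx
formswitch report --kb fx/kb --cohort fx/cohort \
    --overrides fx/overrides.csv --out results
```

which writes `decisions.csv`, `orders.csv`, `review_findings.csv`,
`review_report.json`, `summary.json` and `summary.md`.

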
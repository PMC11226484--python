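# Methods

## The switching model

A hospital formulary is a closed set of products; each product is a name
plus an ordered list of (ingredient, strength) components, a dosage-form
token and an optional ATC code. An outpatient medication record carries
the same attributes (possibly incomplete) plus flags for *prescribed
during the stay* and *self-medication*.

Processing is a strict two-stage cascade. Gates run first, in fixed
order: `NOT_PRESCRIBED → SELF_MEDICATION → MISSING_PRODUCT →
MISSING_STRENGTH`; the first gate that fires is the record's terminal
status (such records appear on the order list as "requires information
completion", not as orders). Eligible records then walk S0→S5 and stop at
the first match, so the six step predicates are evaluated under the
guarantee that all earlier ones failed — the unit tests re-verify this
monotonicity independently.

Design choices where the workflow description leaves room:

* **S0 before S1.** An exclusion-listed drug whose exact product is
  stocked needs no switch and therefore carries no switching risk; the
  exclusion list only constrains *switching*. S1 applies when the exact
  product is not stocked.
* **Ingredient identity is salt-aware** (metoprolol succinate ≠
  tartrate): the two salts are distinct switching entities with different
  release behavior. A packaged synonym map handles international naming
  (salbutamol ↔ albuterol, dipyrone ↔ metamizole, …); matching is
  case-insensitive after whitespace normalization.
* **Strength equality is exact** after unit normalization (mass → mg,
  concentrations → mg/ml; international units are their own dimension).
  No tolerance window: dose rounding is a clinical decision, not an
  equivalence.
* **Dosage forms** match by configurable equivalence classes; the default
  is exact form-token equality, the conservative reading of "switch only
  within the dosage form". Coarser classes (e.g. one class for all
  immediate-release oral solids) can be supplied per knowledge base.
* **Combination products** at S2 prefer a combination-for-combination
  generic; otherwise full decomposition, which requires *every* component
  to have a stocked mono-product at the exact strength and form class
  (all-or-nothing). Either way the original record counts as one switch
  with possibly several order lines.
* **S3 is table-driven only.** An equivalence entry maps one (ingredient,
  strength) to another; nothing is inferred from ATC proximity alone.
  When both sides have coded mono products, agreement at the entry's ATC
  level (4 or 5) is asserted at load time. For a combination record an
  entry may convert one component; the candidate must be a stocked
  combination carrying the converted component plus all remaining
  components unchanged (e.g. ezetimibe/simvastatin →
  ezetimibe/rosuvastatin).
* **S4 is never auto-derived.** It requires an explicit override entry
  (patient, medication identity, stocked target, note); the engine will
  not promote near-miss S3 candidates on its own.
* **Ties** are broken lexicographically by product name everywhere, so
  identical inputs always produce byte-identical outputs.

## Reconciliation conventions

Records from the three sources merge per medication; identity is the
product name when known, the ingredient multiset otherwise. Each field is
filled from the highest-priority source providing it, with the source
recorded per field. Default priority: interview > medication list >
medical documents — in practice the pharmacist interview is the richest
source. Disagreeing strengths are *flagged*, never silently resolved, in
keeping with the safety context. A patient's "main information source" is
the source contributing the most filled fields across their records, ties
going to the priority order (the underlying workflow leaves this
adjudication unspecified; this is a repository convention).

## Review conventions

DDI screening considers the unordered pairs of distinct ingredient
*moieties* (salt-insensitive) over medications prescribed during the
stay; one count per unique pair per patient. Patients with fewer than two
concomitant medications are not assessable and are excluded from the DDI
denominator. PIM screening applies to patients at or above the age
threshold (default 65 years); an ingredient is PIM-positive if
PRISCUS-listed or FORTA C/D. Findings are reported, not auto-applied.
The interaction table and PIM catalogs are user-supplied data: the
packaged defaults are small illustrative sets, not a clinical reference.

## Statistics

Quartiles use linear interpolation between order statistics (the common
"type 7" rule); an independent implementation
(`statistics.quantiles(method="inclusive")`) cross-checks it in the
tests. Percentages round half-up: one decimal for step shares (denominator
= all medications, gates included), integers for review and combination
rates (denominators: assessable patients, patients ≥ 65, and the 23
combination records respectively).

## The deterministic study cohort

`build_paper_fixture()` constructs 100 patients carrying 475 medication
records (511 active ingredients including combination components) plus a
matched knowledge base and two override entries. The construction is
attribute-driven: a record destined to be, say, a generic switch is given
a home product name and a formulary that happens to stock a matching
generic — no step label is stored anywhere, and the verification step
re-derives every marginal by running the real review and switching code.
Fixed design elements:

* Per-patient medication counts and ages are fixed multisets chosen to
  hit the medians/quartiles (4 [2; 7] medications; 71 [64; 80] years,
  73 patients ≥ 65) exactly under the type-7 quartile convention.
* 31 of the 79 assessable patients are wired with exactly one interacting
  pair from a four-pair interaction table (aspirin–ibuprofen,
  aspirin–dipyrone, amlodipine–simvastatin, clopidogrel–omeprazole); the
  assignment procedure provably never completes an interaction pair in
  any other patient.
* The 15 PRISCUS/FORTA-C-D ingredients live in 12 designated patients
  aged ≥ 65.
* The 23 combination products comprise 10 two-component and 13
  three-component records. Four stay on stocked combinations (S0), twelve
  fully decompose to mono-products (S2), one switches a component via the
  statin table onto a stocked combination (S3), one is switched to a
  mono-product by pharmacist override (S4), four have no path onto the
  formulary (S5) and one lacks a product name. In the resolution summary,
  "stays on a combination product" covers S0, S3 and S5 (for S5 the
  original combination is ordered from the wholesaler): 9 records; "to
  mono-products" covers the decompositions and the override: 13 records.
  The published sub-analysis counts (9 vs 13 of 22 determinate records)
  cannot be reconciled with its per-step counts under any disjoint
  labelling, so this resolution-kind convention is the package's
  documented reading; a consequence is that the fixture exercises the
  combo-for-combo S2 path only in unit tests, not in the cohort.
* Named ingredients mirror the published per-drug top list with real ATC
  codes; one published row (bisoprolol) under-accounts its own total by
  3 records, which are carried as generic switches. Filler records use
  synthetic ingredient names (`syndrug-*`, `syncombo-*`).
* Step percentages are computed over the stated 475 records. Note that
  the published percentages for two categories (42.0% generic, 23.9%
  unknown product) correspond to a denominator of 476; the honest values
  over 475 are 42.1% (200/475) and 24.0% (114/475). All counts, and the
  remaining seven percentages, agree with the publication exactly.

The fixture emulates the *structure* of a real admission cohort — source
provenance, incompleteness, combination products, interaction and PIM
wiring — but not free-text product naming, dose schedules, or the
department-level case mix beyond the urology-dominant split. Passing
tests therefore demonstrate that the algorithmic pipeline reproduces the
cohort-level statistics from attribute-level inputs, not that the
packaged interaction or PIM data are clinically complete.

## The stochastic generator

`generate_cohort(GeneratorParams(seed=…))` draws per-patient medication
counts (1 + Poisson), then per medication one categorical draw over the
unconditional gate rates (not-prescribed, missing product, missing
strength, exclusion-listed; their sum must be ≤ 1) and, for the eligible
remainder, conditional draws for formulary coverage, generic and
equivalence availability in cascade order. Every medication gets a unique
synthetic ingredient, so empirical attribute rates are independent
binomial proportions; the tests check recovery within 3·√(p(1−p)/n) at
roughly 10,000 medications. Interaction pairs are added per patient with
probability `ddi_pair_density` between two of their prescribed
ingredients. Defaults approximate the study cohort's rates. All
randomness flows from the single mandatory seed through one
`numpy.random.Generator`.

## Problem sizes and numerics

The deterministic cohort (475 records, ~90 formulary products) runs the
full pipeline in well under a second; property tests use ~1,000-record
cohorts for cascade invariants and ~10,000 for rate recovery. Candidate
search is indexed by ingredient-name set, making cohort-scale runs linear
in practice; a brute-force filter over the whole formulary serves as the
test oracle. Strengths are `Decimal`, so unit conversion is exact;
quartiles are the only floating-point computation.

## Known limitations

* Dose-schedule conversion (e.g. once- vs twice-daily across
  equivalents) is out of scope; administration times pass through
  untouched.
* Discharge-direction switching (formulary → outpatient) is not modeled.
* The packaged equivalence tables contain only a handful of entries;
  real deployments must supply licensed tables.
* Free-text inputs (physician letters) are assumed already structured
  into rows.
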
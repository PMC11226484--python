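"""Deterministic study cohort and seeded stochastic cohort generator.

The **study fixture** is a fully synthetic but deterministic cohort of
100 patients with 475 outpatient medication records (511 active
ingredients counting combination-product components), together with a
matched knowledge base and two pharmacist override entries.  Crucially,
the records are *attribute-driven*: a medication carries a product name,
components, dosage form and flags, and whether a matching product,
generic, equivalence entry or override exists is a property of the
knowledge base -- the switching engine has to re-derive every step label
itself.  Construction verifies all cohort marginals by actually running
review and switching, and refuses to emit a non-conforming fixture.

Named ingredients and their per-step record counts mirror the published
per-drug top list; the remaining records use synthetic ingredient names
("syndrug-NN", "syncombo-XN") with realistic attribute flags.

The **generator** (:func:`generate_cohort`) produces seeded random
cohorts with controllable attribute rates for property testing; every
medication gets a unique synthetic ingredient, so attribute frequencies
are independent Bernoulli draws and converge to the configured rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .knowledge_base import (
    DEFAULT_EXCLUSION,
    EquivalenceEntry,
    ExclusionList,
    Formulary,
    IngredientKey,
    InteractionKB,
    KnowledgeBase,
    PIMCatalog,
    Product,
    StrengthSpec,
)
from .atc import parse_atc
from .medication_review import ReviewSummary, review_report
from .reconciliation import Patient, ReconciledMedication, Source
from .report import combination_resolution, quartiles
from .switching_engine import OverrideEntry, SwitchDecision, decide_cohort

__all__ = [
    "FixtureError",
    "PaperFixture",
    "FIXTURE_STATUS_COUNTS",
    "FIXTURE_COMBO_RESOLUTION",
    "build_paper_fixture",
    "verify_fixture_marginals",
    "VerificationReport",
    "GeneratorParams",
    "generate_cohort",
]


class FixtureError(RuntimeError):
    """The constructed fixture failed its own marginal verification."""


class PaperFixture(NamedTuple):
    patients: list[Patient]
    kb: KnowledgeBase
    overrides: list[OverrideEntry]


#: step/gate marginals of the study cohort (over 475 medications)
FIXTURE_STATUS_COUNTS: dict[str, int] = {
    "S0": 88, "S1": 1, "S2": 200, "S3": 8, "S4": 2, "S5": 39,
    "MISSING_PRODUCT": 114, "MISSING_STRENGTH": 8,
    "NOT_PRESCRIBED": 15, "SELF_MEDICATION": 0,
}

#: how the 23 combination products resolve
FIXTURE_COMBO_RESOLUTION = {"mono": 13, "combination": 9, "unresolved": 1}

FIXTURE_EXPECTED = {
    "n_patients": 100,
    "n_medications": 475,
    "n_active_ingredients": 511,
    "n_combinations": 23,
    "meds_quartiles": (2.0, 4.0, 7.0),
    "age_quartiles": (64.0, 71.0, 80.0),
    "aged_65_plus": 73,
    "assessable": 79,
    "with_ddi": 31,
    "with_pim": 12,
    "priscus_ingredients": 3,
    "forta_cd_ingredients": 12,
}


# --------------------------------------------------------------------------
# record recipes

@dataclass
class _Rec:
    """Internal construction recipe for one medication record."""

    components: tuple[tuple[str, str | None, str | None], ...]
    product: str | None
    form: str
    prescribed: bool = True
    override_target: str | None = None
    index: int = -1

    def ingredient_names(self) -> frozenset[str]:
        return frozenset(name for name, _, _ in self.components)


def _display(name: str, salt: str | None) -> str:
    base = name.title()
    return f"{base} ({salt})" if salt else base


# (name, salt, strength, form, atc, {category: count})
# categories: S0 exact product stocked; S2 home product with stocked
# generic; S3 home product reachable only via an equivalence entry;
# S4 home product needing a pharmacist override; S5 home product with no
# path onto the formulary; S1 exclusion-listed; NP not prescribed during
# the stay; MP product name unknown; MS strength unknown.
_NAMED_SINGLES: list[tuple[str, str | None, str, str, str | None, dict[str, int]]] = [
    ("acetylsalicylic acid", None, "100 mg", "tablet", "B01AC06",
     {"S0": 3, "S2": 11, "NP": 2, "MP": 13}),
    ("tamsulosin", None, "0.4 mg", "capsule", "G04CA02",
     {"S0": 6, "S2": 11, "MP": 10}),
    ("amlodipine", None, "5 mg", "tablet", "C08CA01",
     {"S0": 2, "S2": 12, "MP": 7}),
    ("metoprolol", "succinate", "95 mg", "tablet", "C07AB02",
     {"S0": 7, "S2": 6, "MP": 3, "MS": 1}),
    ("metoprolol", "tartrate", "50 mg", "tablet", "C07AB02", {"S5": 2}),
    ("atorvastatin", None, "40 mg", "tablet", "C10AA05",
     {"S2": 9, "MP": 8, "MS": 1}),
    ("ramipril", None, "5 mg", "tablet", "C09AA05", {"S2": 8, "MP": 9}),
    ("l-thyroxine", None, "100 mcg", "tablet", "H03AA01",
     {"S0": 2, "S2": 7, "MP": 6, "NP": 1}),
    ("colecalciferol", None, "20000 iu", "tablet", "A11CC05",
     {"S0": 8, "S2": 7}),
    ("simvastatin", None, "40 mg", "tablet", "C10AA01",
     {"S0": 1, "S2": 8, "MP": 6}),
    ("torasemide", None, "10 mg", "tablet", "C03CA04",
     {"S0": 1, "S2": 6, "MP": 7, "MS": 1}),
    ("candesartan", None, "8 mg", "tablet", "C09CA06",
     {"S0": 1, "S2": 6, "MP": 7}),
    ("dipyrone", None, "500 mg", "tablet", "N02BB02", {"S2": 12, "MP": 2}),
    ("pantoprazole", None, "40 mg", "tablet", "A02BC02",
     {"S0": 1, "S2": 10, "MP": 3}),
    ("metformin", None, "1000 mg", "tablet", "A10BA02", {"S2": 8, "MP": 4}),
    # the published top list accounts for only 9 of 12 bisoprolol records;
    # the 3 unaccounted ones are carried as generic switches
    ("bisoprolol", None, "5 mg", "tablet", "C07AB07", {"S2": 5, "MP": 7}),
    ("rosuvastatin", None, "10 mg", "tablet", "C10AA07", {"S0": 1, "S2": 10}),
    ("allopurinol", None, "300 mg", "tablet", "M04AA01",
     {"S2": 5, "MP": 4, "MS": 1}),
    ("ibuprofen", None, "600 mg", "tablet", "M01AE01", {"S0": 1, "MP": 8}),
    ("apixaban", None, "5 mg", "tablet", "B01AF02", {"S0": 8}),
    ("rivaroxaban", None, "20 mg", "tablet", "B01AF01", {"S0": 8}),
    ("omeprazole", None, "20 mg", "tablet", "A02BC01", {"S3": 6}),
    ("omeprazole", None, "10 mg", "tablet", "A02BC01", {"S4": 1}),
    ("hydrochlorothiazide", None, "25 mg", "tablet", "C03AA03",
     {"S0": 1, "S2": 6}),
    ("salbutamol", None, "0.1 mg", "inhalation", "R03AC02", {"S0": 1, "S2": 5}),
    ("insulin glargine", None, "100 iu/ml", "injection", "A10AE04",
     {"S0": 3, "S2": 2}),
    ("empagliflozin", None, "10 mg", "tablet", "A10BK03", {"S0": 5}),
    ("carbamazepine", None, "200 mg", "tablet", "N03AF01", {"S1": 1}),
    ("clopidogrel", None, "75 mg", "tablet", "B01AC04", {"S2": 1}),
    ("lansoprazole", None, "30 mg", "tablet", "A02BC03", {"S3": 1}),
    # urologicals (G04) and A10B antidiabetics without equivalence tables
    ("solifenacin", None, "5 mg", "tablet", "G04BD08", {"S5": 1}),
    ("desfesoterodine", None, "3.5 mg", "tablet", "G04BD13", {"S5": 1}),
    ("oxybutynin", None, "5 mg", "tablet", "G04BD04", {"S5": 1}),
    ("silodosin", None, "8 mg", "capsule", "G04CA04", {"S5": 1}),
    ("alfuzosin", None, "10 mg", "tablet", "G04CA01", {"S5": 1}),
    ("semaglutide", None, "1 mg", "injection", "A10BJ06", {"S5": 1}),
    ("liraglutide", None, "6 mg/ml", "injection", "A10BJ02", {"S5": 1}),
    ("dulaglutide", None, "1.5 mg", "injection", "A10BJ05", {"S5": 1}),
    ("pioglitazone", None, "30 mg", "tablet", "A10BG03", {"S5": 1}),
    ("vildagliptin", None, "50 mg", "tablet", "A10BH02", {"S5": 1}),
    # non-formulary drugs carried by the PIM-positive patients
    ("amitriptyline", None, "25 mg", "tablet", "N06AA09", {"S5": 1}),
    ("zopiclone", None, "7.5 mg", "tablet", "N05CF01", {"S5": 1}),
    ("digoxin", None, "0.2 mg", "tablet", "C01AA05", {"S5": 1}),
    ("amiodarone", None, "200 mg", "tablet", "C01BD01", {"S5": 1}),
    ("doxazosin", None, "4 mg", "tablet", "C02CA04", {"S5": 1}),
    ("moxonidine", None, "0.3 mg", "tablet", "C02AC05", {"S5": 1}),
    ("oxazepam", None, "10 mg", "tablet", "N05BA04", {"S5": 1}),
    ("zolpidem", None, "10 mg", "tablet", "N05CF02", {"S5": 1}),
    ("diclofenac", None, "75 mg", "tablet", "M01AB05", {"S5": 1}),
    ("etoricoxib", None, "90 mg", "tablet", "M01AH05", {"S5": 1}),
    ("quetiapine", None, "25 mg", "tablet", "N05AH04", {"S5": 1}),
]

# synthetic filler counts per category (singles)
_SYNTHETIC_SINGLES = {"S0": 24, "S2": 33, "S5": 12, "NP": 12, "MP": 9, "MS": 4}

_PRISCUS = ("oxybutynin", "amitriptyline", "zopiclone")
_FORTA_CD = {
    "solifenacin": "C", "desfesoterodine": "C", "pioglitazone": "D",
    "digoxin": "C", "amiodarone": "C", "doxazosin": "C", "moxonidine": "C",
    "oxazepam": "C", "zolpidem": "D", "diclofenac": "C", "etoricoxib": "C",
    "quetiapine": "C",
}
_FORTA_AB = {"ramipril": "A", "metformin": "A", "apixaban": "B"}

#: ingredient-moiety interaction pairs wired into the fixture
_INTERACTIONS = (
    ("acetylsalicylic acid", "ibuprofen", "moderate"),
    ("acetylsalicylic acid", "dipyrone", "moderate"),
    ("amlodipine", "simvastatin", "moderate"),
    ("clopidogrel", "omeprazole", "major"),
)

_EQUIVALENCE = (
    ("ppi", "omeprazole", "20 mg", "pantoprazole", "40 mg", 4),
    ("ppi", "lansoprazole", "30 mg", "pantoprazole", "40 mg", 4),
    ("statin", "simvastatin", "20 mg", "rosuvastatin", "10 mg", 4),
)

# total medications per patient, a fixed multiset chosen so the quartiles
# under linear interpolation are exactly Q25=2, median=4, Q75=7
_MED_COUNTS = ([16, 15] + [12] * 8 + [9] * 10 + [3] * 23 + [4] * 12
               + [5] * 10 + [6] * 3 + [7] * 6 + [2] * 5 + [1] * 21)

# patient ages, a fixed multiset with Q25=64, median=71, Q75=80 and
# exactly 73 values >= 65
_AGES = (
    [46, 48, 50, 52, 53, 54, 55, 56, 57, 58, 59, 60, 60, 61, 61, 62, 62,
     62, 63, 63, 63, 63, 64, 64, 64, 64, 64]
    + [65] * 4 + [66] * 4 + [67] * 4 + [68] * 4 + [69] * 3 + [70] * 3
    + [71] * 4
    + [72] * 3 + [73] * 3 + [74] * 3 + [75] * 3 + [76] * 3
    + [77] * 2 + [78] * 2 + [79] * 2
    + [80] * 4
    + [81] * 3 + [82] * 3 + [83] * 3 + [84] * 2 + [85] * 2 + [86] * 2
    + [87] * 2 + [88, 89, 90, 91, 92]
)

_DEPARTMENTS = (["urology"] * 87 + ["general surgery"] * 8
                + ["trauma surgery"] * 4 + ["internal medicine"] * 1)

_MAIN_SOURCES = ([Source.INTERVIEW] * 64 + [Source.MEDICATION_LIST] * 21
                 + [Source.MEDICAL_DOCUMENTS] * 15)


class _Builder:
    def __init__(self) -> None:
        self.records: list[_Rec] = []
        self.products: dict[str, Product] = {}
        self.override_protos: list[tuple[int, str, str]] = []  # rec idx, target, note

    # -- formulary helpers -------------------------------------------------
    def register(self, name: str, components, form: str,
                 atc: str | None) -> str:
        comps = tuple(
            (IngredientKey.make(n, s), StrengthSpec.parse(st))
            for n, s, st in components
        )
        if name not in self.products:
            self.products[name] = Product(
                product_name=name, components=comps, dosage_form=form,
                atc=parse_atc(atc) if atc else None,
            )
        return name

    def inhouse(self, name, salt, strength, form, atc) -> str:
        label = f"{_display(name, salt)} Inhouse {strength}"
        return self.register(label, [(name, salt, strength)], form, atc)

    # -- record helpers ----------------------------------------------------
    def add(self, rec: _Rec) -> int:
        rec.index = len(self.records)
        self.records.append(rec)
        return rec.index

    def add_single(self, name, salt, strength, form, atc, category: str,
                   override_target: str | None = None) -> int:
        home = f"{_display(name, salt)} Home {strength}"
        comp = ((name, salt, strength),)
        if category == "S0":
            product = self.inhouse(name, salt, strength, form, atc)
            return self.add(_Rec(comp, product, form))
        if category == "S2":
            self.inhouse(name, salt, strength, form, atc)
            return self.add(_Rec(comp, home, form))
        if category in ("S3", "S5", "S1"):
            return self.add(_Rec(comp, home, form))
        if category == "S4":
            return self.add(_Rec(comp, home, form,
                                 override_target=override_target))
        if category == "NP":
            return self.add(_Rec(comp, home, form, prescribed=False))
        if category == "MP":
            return self.add(_Rec(comp, None, form))
        if category == "MS":
            return self.add(_Rec(((name, salt, None),), home, form))
        raise AssertionError(category)


def _build_records(builder: _Builder) -> dict[str, list[int]]:
    """Create all 475 record recipes; returns per-ingredient pools of
    prescribed single records (used for interaction wiring)."""
    pools: dict[str, list[int]] = {}
    for name, salt, strength, form, atc, cats in _NAMED_SINGLES:
        for category, n in cats.items():
            for _ in range(n):
                idx = builder.add_single(
                    name, salt, strength, form, atc, category,
                    override_target=("Pantoprazole Inhouse 40 mg"
                                     if category == "S4" else None),
                )
                if category == "S4":
                    builder.override_protos.append(
                        (idx, "Pantoprazole Inhouse 40 mg",
                         "interaction potential with clopidogrel; switch "
                         "within the PPI group"))
                if category != "NP":
                    pools.setdefault(name, []).append(idx)

    for i in range(_SYNTHETIC_SINGLES["S0"]):
        builder.add_single(f"syndrug-a{i:02d}", None, "10 mg", "tablet",
                           None, "S0")
    for i in range(_SYNTHETIC_SINGLES["S2"]):
        builder.add_single(f"syndrug-b{i:02d}", None, "10 mg", "tablet",
                           None, "S2")
    for i in range(_SYNTHETIC_SINGLES["S5"]):
        builder.add_single(f"syndrug-c{i:02d}", None, "10 mg", "tablet",
                           None, "S5")
    for i in range(_SYNTHETIC_SINGLES["NP"]):
        builder.add_single(f"syndrug-d{i:02d}", None, "10 mg", "tablet",
                           None, "NP")
    for i in range(_SYNTHETIC_SINGLES["MP"]):
        builder.add_single(f"syndrug-e{i:02d}", None, "10 mg", "tablet",
                           None, "MP")
    for i in range(_SYNTHETIC_SINGLES["MS"]):
        builder.add_single(f"syndrug-f{i:02d}", None, "10 mg", "tablet",
                           None, "MS")

    _build_combinations(builder)
    return pools


def _build_combinations(b: _Builder) -> None:
    # stays on the stocked combination product (no switch required)
    cande_hct = b.register(
        "Candesartan/HCT Inhouse 16/12.5 mg",
        [("candesartan", None, "16 mg"), ("hydrochlorothiazide", None, "12.5 mg")],
        "tablet", "C09DA06")
    duta_tam = b.register(
        "Dutasteride/Tamsulosin Inhouse 0.5/0.4 mg",
        [("dutasteride", None, "0.5 mg"), ("tamsulosin", None, "0.4 mg")],
        "capsule", "G04CA52")
    for _ in range(2):
        b.add(_Rec((("candesartan", None, "16 mg"),
                    ("hydrochlorothiazide", None, "12.5 mg")),
                   cande_hct, "tablet"))
    for _ in range(2):
        b.add(_Rec((("dutasteride", None, "0.5 mg"),
                    ("tamsulosin", None, "0.4 mg")),
                   duta_tam, "capsule"))

    # generic switching by full decomposition: every component has a
    # stocked mono-product at the exact strength
    b.inhouse("ezetimibe", None, "10 mg", "tablet", "C10AX09")
    b.inhouse("sitagliptin", None, "50 mg", "tablet", "A10BH01")
    b.inhouse("hydrochlorothiazide", None, "12.5 mg", "tablet", "C03AA03")
    for _ in range(2):
        b.add(_Rec((("ezetimibe", None, "10 mg"),
                    ("atorvastatin", None, "40 mg")),
                   "Ezetimibe/Atorvastatin Home 10/40 mg", "tablet"))
    for _ in range(3):
        b.add(_Rec((("metformin", None, "1000 mg"),
                    ("sitagliptin", None, "50 mg")),
                   "Metformin/Sitagliptin Home 1000/50 mg", "tablet"))
    for _ in range(2):
        b.add(_Rec((("ramipril", None, "5 mg"), ("amlodipine", None, "5 mg"),
                    ("hydrochlorothiazide", None, "12.5 mg")),
                   "Ramipril/Amlodipine/HCT Home 5/5/12.5 mg", "tablet"))
    for _ in range(3):
        b.add(_Rec((("candesartan", None, "8 mg"), ("amlodipine", None, "5 mg"),
                    ("hydrochlorothiazide", None, "12.5 mg")),
                   "Candesartan/Amlodipine/HCT Home 8/5/12.5 mg", "tablet"))
    for tag in ("a", "b"):
        comps = tuple((f"syncombo-{tag}{j}", None, f"{10 * (j + 1)} mg")
                      for j in range(3))
        for n, s, st in comps:
            b.inhouse(n, s, st, "tablet", None)
        b.add(_Rec(comps, f"Syncombo-{tag.upper()} Home", "tablet"))

    # therapeutically equivalent switch of one component (statin table);
    # not decomposable because no 20 mg simvastatin mono is stocked
    b.register("Ezetimibe/Rosuvastatin Inhouse 10/10 mg",
               [("ezetimibe", None, "10 mg"), ("rosuvastatin", None, "10 mg")],
               "tablet", "C10BA06")
    b.add(_Rec((("ezetimibe", None, "10 mg"), ("simvastatin", None, "20 mg")),
               "Ezetimibe/Simvastatin Home 10/20 mg", "tablet"))

    # patient-individual switch by pharmacist override, onto a mono-product
    idx = b.add(_Rec((("olmesartan", None, "20 mg"),
                      ("amlodipine", None, "5 mg"),
                      ("hydrochlorothiazide", None, "12.5 mg")),
                     "Olmesartan/Amlodipine/HCT Home 20/5/12.5 mg", "tablet",
                     override_target="Amlodipine Inhouse 5 mg"))
    b.override_protos.append(
        (idx, "Amlodipine Inhouse 5 mg",
         "no olmesartan product stocked; continue the calcium-channel "
         "blocker component only per ward agreement"))

    # no path onto the formulary: wholesaler order of the original combo
    for tag in ("c", "d", "e", "f"):
        comps = tuple((f"syncombo-{tag}{j}", None, f"{10 * (j + 1)} mg")
                      for j in range(3))
        b.add(_Rec(comps, f"Syncombo-{tag.upper()} Home", "tablet"))

    # combination with unknown product name (ingredients reported only)
    b.add(_Rec(tuple((f"syncombo-g{j}", None, f"{10 * (j + 1)} mg")
                     for j in range(3)),
               None, "tablet"))


def _assign_to_patients(
    builder: _Builder, pools: dict[str, list[int]]
) -> list[list[int]]:
    """Deterministically distribute records over the 100 patients."""
    records = builder.records
    n_pat = len(_MED_COUNTS)
    capacity = list(_MED_COUNTS)
    assigned: list[list[int]] = [[] for _ in range(n_pat)]
    names_of: list[set[str]] = [set() for _ in range(n_pat)]
    prescribed_names: list[set[str]] = [set() for _ in range(n_pat)]
    placed: set[int] = set()

    interacting = [frozenset((a, b)) for a, b, _ in _INTERACTIONS]
    ddi_patients = set(range(20, 51))  # the 31 patients wired with a pair
    pim_patients = list(range(55, 67))  # 12 patients aged >= 65

    def place(p: int, idx: int) -> None:
        rec = records[idx]
        if capacity[p] <= 0:
            raise FixtureError(f"patient {p} over capacity")
        if names_of[p] & rec.ingredient_names():
            raise FixtureError(f"duplicate ingredient for patient {p}")
        assigned[p].append(idx)
        names_of[p] |= rec.ingredient_names()
        if rec.prescribed:
            prescribed_names[p] |= rec.ingredient_names()
        capacity[p] -= 1
        placed.add(idx)

    def pop_pool(name: str) -> int:
        return pools[name].pop(0)

    # not-prescribed records go to high-capacity patients so that 79
    # patients keep >= 2 concomitant medications
    np_records = [r.index for r in records
                  if not r.prescribed and r.index not in placed]
    assert len(np_records) == 15
    for p, idx in enumerate(np_records):
        place(p, idx)  # patients 0..14 have capacity >= 9

    # interaction wiring: 31 designated patients receive one knowledge-base
    # pair each
    pair_plan = ([("acetylsalicylic acid", "ibuprofen")] * 9
                 + [("acetylsalicylic acid", "dipyrone")] * 13
                 + [("amlodipine", "simvastatin")] * 8
                 + [("omeprazole", "clopidogrel")] * 1)
    for p, (a, bname) in zip(sorted(ddi_patients), pair_plan):
        place(p, pop_pool(a))
        place(p, pop_pool(bname))

    # PIM wiring: the PRISCUS/FORTA-C-D ingredients live in 12 designated
    # elderly patients
    pim_names = list(_PRISCUS) + list(_FORTA_CD)
    assert len(pim_names) == 15
    for i, name in enumerate(pim_names):
        p = pim_patients[i] if i < 12 else pim_patients[11 - (i - 12)]
        place(p, pop_pool(name))

    # everything else: spread deterministically, never duplicating an
    # ingredient within a patient and never completing an interaction pair
    # outside the designated patients
    remaining = [r.index for r in records if r.index not in placed]
    freq: dict[str, int] = {}
    for idx in remaining:
        for n in records[idx].ingredient_names():
            freq[n] = freq.get(n, 0) + 1
    remaining.sort(key=lambda i: (-max(freq[n] for n in
                                       records[i].ingredient_names()), i))

    def allowed(p: int, idx: int) -> bool:
        rec = records[idx]
        if capacity[p] <= 0:
            return False
        if names_of[p] & rec.ingredient_names():
            return False
        if p not in ddi_patients and rec.prescribed:
            combined = prescribed_names[p] | rec.ingredient_names()
            for pair in interacting:
                if pair <= combined and not pair <= prescribed_names[p]:
                    return False
        return True

    for idx in remaining:
        candidates = [p for p in range(n_pat) if allowed(p, idx)]
        if not candidates:
            raise FixtureError(
                f"no placement for record {idx} "
                f"({records[idx].ingredient_names()})"
            )
        best = max(candidates, key=lambda p: (capacity[p], -p))
        place(best, idx)

    if any(c != 0 for c in capacity):
        raise FixtureError("capacity not exhausted")
    return assigned


def _materialize(
    builder: _Builder, assigned: list[list[int]]
) -> tuple[list[Patient], list[OverrideEntry]]:
    ages_desc = sorted(_AGES, reverse=True)
    pim_patients = list(range(55, 67))
    age_of: dict[int, int] = {}
    for i, p in enumerate(pim_patients):
        age_of[p] = ages_desc[i]
    rest = ages_desc[len(pim_patients):]
    j = 0
    for p in range(len(_MED_COUNTS)):
        if p not in age_of:
            age_of[p] = rest[j]
            j += 1

    patients: list[Patient] = []
    rec_to_pid: dict[int, str] = {}
    for p, rec_ids in enumerate(assigned):
        pid = f"P{p + 1:03d}"
        source = _MAIN_SOURCES[p]
        meds = []
        for idx in sorted(rec_ids):
            rec = builder.records[idx]
            rec_to_pid[idx] = pid
            components = tuple(
                (IngredientKey.make(n, s),
                 StrengthSpec.parse(st) if st else None)
                for n, s, st in rec.components
            )
            prov = {"ingredients": source.value}
            if rec.product is not None:
                prov["product_name"] = source.value
            meds.append(
                ReconciledMedication(
                    patient_id=pid,
                    product_name=rec.product,
                    components=components,
                    dosage_form=rec.form,
                    administration_times="1-0-0",
                    prescribed_during_stay=rec.prescribed,
                    provenance=prov,
                )
            )
        patients.append(
            Patient(patient_id=pid, age=age_of[p],
                    department=_DEPARTMENTS[p], medications=meds,
                    main_source=source)
        )

    overrides = [
        OverrideEntry(
            patient_id=rec_to_pid[idx],
            medication=builder.records[idx].product or "",
            target_product=target,
            note=note,
        )
        for idx, target, note in builder.override_protos
    ]
    return patients, overrides


def _build_kb(builder: _Builder) -> KnowledgeBase:
    formulary = Formulary(
        builder.products[k] for k in sorted(builder.products)
    )
    entries = tuple(
        EquivalenceEntry(
            source=(IngredientKey.make(src), StrengthSpec.parse(sst)),
            target=(IngredientKey.make(tgt), StrengthSpec.parse(tst)),
            match_level=level, table_id=table,
        )
        for table, src, sst, tgt, tst, level in _EQUIVALENCE
    )
    forta = {**_FORTA_CD, **_FORTA_AB}
    return KnowledgeBase(
        formulary=formulary,
        exclusion=DEFAULT_EXCLUSION,
        equivalence=entries,
        interactions=InteractionKB(_INTERACTIONS),
        pim=PIMCatalog(frozenset(_PRISCUS), forta),
    )


def build_paper_fixture(verify: bool = True) -> PaperFixture:
    """Construct the deterministic 100-patient / 475-medication cohort.

    With ``verify=True`` (default) the full pipeline is run on the result
    and every cohort marginal checked; a non-conforming fixture raises
    :class:`FixtureError` instead of being returned.
    """
    builder = _Builder()
    pools = _build_records(builder)
    if len(builder.records) != 475:
        raise FixtureError(
            f"expected 475 medication records, built {len(builder.records)}"
        )
    assigned = _assign_to_patients(builder, pools)
    patients, overrides = _materialize(builder, assigned)
    kb = _build_kb(builder)
    fixture = PaperFixture(patients, kb, overrides)
    if verify:
        decisions = decide_cohort(patients, kb, overrides)
        review = review_report(patients, kb)
        report = verify_fixture_marginals(patients, decisions, review)
        if not report.ok:
            raise FixtureError(
                "fixture verification failed:\n" + report.describe(failed_only=True)
            )
    return fixture


# --------------------------------------------------------------------------
# marginal verification

@dataclass(frozen=True)
class Check:
    name: str
    expected: object
    observed: object

    @property
    def passed(self) -> bool:
        return self.expected == self.observed


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[Check, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]

    def describe(self, failed_only: bool = False) -> str:
        lines = []
        for c in self.checks:
            if failed_only and c.passed:
                continue
            mark = "ok " if c.passed else "FAIL"
            lines.append(f"[{mark}] {c.name}: expected {c.expected}, "
                         f"observed {c.observed}")
        return "\n".join(lines)


def verify_fixture_marginals(
    cohort: Sequence[Patient],
    decisions: Sequence[SwitchDecision],
    review: ReviewSummary,
) -> VerificationReport:
    """Compare pipeline outputs on the study fixture against every
    published cohort marginal."""
    checks: list[Check] = []
    exp = FIXTURE_EXPECTED

    checks.append(Check("n_patients", exp["n_patients"], len(cohort)))
    checks.append(Check("n_medications", exp["n_medications"], len(decisions)))
    n_ing = sum(len(m.components) for p in cohort for m in p.medications)
    checks.append(Check("n_active_ingredients",
                        exp["n_active_ingredients"], n_ing))

    counts = {k: 0 for k in FIXTURE_STATUS_COUNTS}
    for d in decisions:
        counts[d.status.value] += 1
    for status, n in FIXTURE_STATUS_COUNTS.items():
        checks.append(Check(f"status:{status}", n, counts[status]))

    combos = [d for d in decisions if d.medication.is_combination]
    checks.append(Check("n_combinations", exp["n_combinations"], len(combos)))
    res = {"mono": 0, "combination": 0, "unresolved": 0}
    for d in combos:
        res[combination_resolution(d)] += 1
    for kind, n in FIXTURE_COMBO_RESOLUTION.items():
        checks.append(Check(f"combination:{kind}", n, res[kind]))

    med_q = (quartiles([len(p.medications) for p in cohort])
             if cohort else (0.0, 0.0, 0.0))
    age_q = (quartiles([p.age for p in cohort]) if cohort else (0.0, 0.0, 0.0))
    checks.append(Check("meds_quartiles", exp["meds_quartiles"], med_q))
    checks.append(Check("age_quartiles", exp["age_quartiles"], age_q))
    checks.append(Check("aged_65_plus", exp["aged_65_plus"],
                        sum(1 for p in cohort if p.age >= 65)))

    checks.append(Check("assessable", exp["assessable"], review.assessable))
    checks.append(Check("with_ddi", exp["with_ddi"], review.with_ddi))
    checks.append(Check("with_pim", exp["with_pim"], review.with_pim))
    checks.append(Check(
        "priscus_ingredients", exp["priscus_ingredients"],
        len({f.ingredient for f in review.pim_findings
             if f.catalog == "PRISCUS"})))
    checks.append(Check(
        "forta_cd_ingredients", exp["forta_cd_ingredients"],
        len({f.ingredient for f in review.pim_findings
             if f.catalog == "FORTA"})))
    return VerificationReport(tuple(checks))


# --------------------------------------------------------------------------
# stochastic cohort generator

@dataclass(frozen=True)
class GeneratorParams:
    """Attribute rates for random cohorts; all probabilities in [0, 1].

    The four unconditional rates (not-prescribed, missing product,
    missing strength, exclusion-listed) must sum to at most 1; the
    conditional availabilities (formulary coverage, generic,
    equivalence) apply to the remaining eligible mass in cascade order.
    """

    seed: int
    n_patients: int = 100
    meds_per_patient_mean: float = 4.75
    formulary_coverage: float = 0.22
    generic_availability: float = 0.70
    equivalence_availability: float = 0.10
    exclusion_probability: float = 0.003
    missing_product_rate: float = 0.239
    missing_strength_rate: float = 0.017
    not_prescribed_rate: float = 0.032
    ddi_pair_density: float = 0.39

    def __post_init__(self) -> None:
        probs = {
            "formulary_coverage": self.formulary_coverage,
            "generic_availability": self.generic_availability,
            "equivalence_availability": self.equivalence_availability,
            "exclusion_probability": self.exclusion_probability,
            "missing_product_rate": self.missing_product_rate,
            "missing_strength_rate": self.missing_strength_rate,
            "not_prescribed_rate": self.not_prescribed_rate,
            "ddi_pair_density": self.ddi_pair_density,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        gates = (self.not_prescribed_rate + self.missing_product_rate
                 + self.missing_strength_rate + self.exclusion_probability)
        if gates > 1.0:
            raise ValueError("gate rates sum to more than 1")


def generate_cohort(
    params: GeneratorParams,
) -> tuple[list[Patient], KnowledgeBase]:
    """Seeded random cohort with the configured attribute frequencies.

    Every medication receives a unique synthetic ingredient, so each
    attribute is an independent Bernoulli draw: empirical rates converge
    to the parameters with binomial fluctuations.
    """
    rng = np.random.default_rng(params.seed)
    products: dict[str, Product] = {}
    entries: list[EquivalenceEntry] = []
    exclusion: set[IngredientKey] = set()
    interactions: list[tuple[str, str, str]] = []
    patients: list[Patient] = []
    med_no = 0

    def mono(label: str, ing: str, strength: str) -> None:
        if label not in products:
            products[label] = Product(
                label,
                ((IngredientKey.make(ing), StrengthSpec.parse(strength)),),
                "tablet",
            )

    for p in range(params.n_patients):
        pid = f"G{p + 1:04d}"
        n_meds = 1 + rng.poisson(max(params.meds_per_patient_mean - 1, 0.0))
        age = int(rng.integers(40, 95))
        meds: list[ReconciledMedication] = []
        for _ in range(n_meds):
            ing = f"gen-{med_no:05d}"
            med_no += 1
            strength = "10 mg"
            home = f"{ing.title()} Home"
            u = rng.random()
            prescribed = True
            product: str | None = home
            comp_strength: str | None = strength
            thresholds = np.cumsum([
                params.not_prescribed_rate,
                params.missing_product_rate,
                params.missing_strength_rate,
                params.exclusion_probability,
            ])
            if u < thresholds[0]:
                prescribed = False
            elif u < thresholds[1]:
                product = None
            elif u < thresholds[2]:
                comp_strength = None
            elif u < thresholds[3]:
                exclusion.add(IngredientKey.make(ing))
            else:
                v = rng.random()
                w = rng.random()
                x = rng.random()
                if v < params.formulary_coverage:
                    product = f"{ing.title()} Inhouse"
                    mono(product, ing, strength)
                elif w < params.generic_availability:
                    mono(f"{ing.title()} Inhouse", ing, strength)
                elif x < params.equivalence_availability:
                    alt = f"{ing}-alt"
                    mono(f"{alt.title()} Inhouse", alt, strength)
                    entries.append(
                        EquivalenceEntry(
                            source=(IngredientKey.make(ing),
                                    StrengthSpec.parse(strength)),
                            target=(IngredientKey.make(alt),
                                    StrengthSpec.parse(strength)),
                            match_level=4,
                            table_id="generated",
                        )
                    )
            meds.append(
                ReconciledMedication(
                    patient_id=pid,
                    product_name=product,
                    components=(
                        (IngredientKey.make(ing),
                         StrengthSpec.parse(comp_strength)
                         if comp_strength else None),
                    ),
                    dosage_form="tablet",
                    prescribed_during_stay=prescribed,
                    provenance={"ingredients": "interview"},
                )
            )
        concomitant = [m for m in meds if m.prescribed_during_stay]
        if len(concomitant) >= 2 and rng.random() < params.ddi_pair_density:
            i, j = rng.choice(len(concomitant), size=2, replace=False)
            interactions.append(
                (concomitant[int(i)].components[0][0].name,
                 concomitant[int(j)].components[0][0].name, "moderate")
            )
        patients.append(
            Patient(pid, age=age, department="urology", medications=meds,
                    main_source=Source.INTERVIEW)
        )

    kb = KnowledgeBase(
        formulary=Formulary(products[k] for k in sorted(products)),
        exclusion=ExclusionList(frozenset(exclusion)),
        equivalence=tuple(entries),
        interactions=InteractionKB(interactions),
        pim=PIMCatalog(),
    )
    return patients, kb
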
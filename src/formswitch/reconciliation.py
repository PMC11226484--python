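"""Medication reconciliation: merging multi-source medication information.

At hospital admission, what a patient actually takes is pieced together
from up to three sources: a pharmacist-led **interview** (including a
brown-bag review of packages brought along), **medication lists** the
patient brings (e.g. the standardized list issued by the general
practitioner), and **medical documents** in the clinic information system
(physician's letters, discharge letters).  Each source may know some
fields of a medication and miss others; this module collapses the
per-source records into one :class:`ReconciledMedication` per medication,
records per-field provenance, surfaces conflicts instead of silently
overriding them, and flags completeness -- a medication without a product
name or strength cannot enter the switching cascade.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .knowledge_base import IngredientKey, KBError, StrengthSpec
from .schemas import load_schema, validate_row

__all__ = [
    "Source",
    "Completeness",
    "SourceRecord",
    "ReconciledMedication",
    "Patient",
    "DEFAULT_PRIORITY",
    "merge_sources",
    "completeness_status",
    "classify_main_source",
    "load_sources",
    "load_cohort",
    "save_cohort",
]


class Source(str, enum.Enum):
    INTERVIEW = "interview"
    MEDICATION_LIST = "medication_list"
    MEDICAL_DOCUMENTS = "medical_documents"


#: The interview proved the richest source in practice, so it wins ties
#: and field conflicts by default.
DEFAULT_PRIORITY: tuple[Source, ...] = (
    Source.INTERVIEW,
    Source.MEDICATION_LIST,
    Source.MEDICAL_DOCUMENTS,
)


class Completeness(str, enum.Enum):
    COMPLETE = "COMPLETE"
    MISSING_PRODUCT = "MISSING_PRODUCT"
    MISSING_STRENGTH = "MISSING_STRENGTH"


MedComponent = tuple[IngredientKey, StrengthSpec | None]


@dataclass(frozen=True)
class SourceRecord:
    """One medication as reported by one information source."""

    patient_id: str
    source: Source
    product_name: str | None = None
    ingredients: tuple[MedComponent, ...] = ()
    dosage_form: str | None = None
    administration_times: str | None = None
    prescribed_during_stay: bool = True
    self_medication: bool = False

    def __post_init__(self) -> None:
        if not self.product_name and not self.ingredients:
            raise ValueError(
                "source record needs a product name or at least one ingredient"
            )

    def identity(self) -> tuple:
        """Cross-source medication identity: product name first, the
        ingredient-key multiset as fallback."""
        if self.product_name:
            return ("name", self.product_name.strip().lower())
        return ("ingredients", tuple(sorted(i for i, _ in self.ingredients)))


@dataclass(frozen=True)
class ReconciledMedication:
    """One outpatient medication after source merging."""

    patient_id: str
    product_name: str | None = None
    components: tuple[MedComponent, ...] = ()
    dosage_form: str | None = None
    administration_times: str | None = None
    prescribed_during_stay: bool = True
    self_medication: bool = False
    #: field name -> source that supplied it
    provenance: Mapping[str, str] = field(default_factory=dict)
    #: field names with conflicting non-missing values across sources
    conflicts: tuple[str, ...] = ()

    @property
    def is_combination(self) -> bool:
        return len(self.components) >= 2

    def ingredient_keys(self) -> tuple[IngredientKey, ...]:
        return tuple(ing for ing, _ in self.components)

    def display_name(self) -> str:
        if self.product_name:
            return self.product_name
        return "/".join(str(i) for i, _ in self.components) or "<unknown>"

    def identity(self) -> tuple:
        if self.product_name:
            return ("name", self.product_name.strip().lower())
        return ("ingredients", tuple(sorted(self.ingredient_keys())))


@dataclass
class Patient:
    patient_id: str
    age: int
    department: str = ""
    medications: list[ReconciledMedication] = field(default_factory=list)
    main_source: Source | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")


def completeness_status(med: ReconciledMedication) -> Completeness:
    """MISSING_PRODUCT if the product name is unknown (takes precedence),
    MISSING_STRENGTH if any component strength is unknown, else COMPLETE."""
    if not med.product_name:
        return Completeness.MISSING_PRODUCT
    if not med.components or any(st is None for _, st in med.components):
        return Completeness.MISSING_STRENGTH
    return Completeness.COMPLETE


def merge_sources(
    records: Sequence[SourceRecord],
    priority: Sequence[Source] = DEFAULT_PRIORITY,
) -> list[ReconciledMedication]:
    """Collapse per-source records into one medication each.

    Records referring to the same medication (same product name, or same
    ingredient multiset when no name is known) are merged field-wise: each
    field is taken from the highest-priority source that provides it, and
    the providing source is recorded in ``provenance``.  Strength values
    that disagree between sources are flagged in ``conflicts`` rather than
    silently overridden.
    """
    if sorted(priority, key=lambda s: s.value) != sorted(Source, key=lambda s: s.value):
        raise ValueError("priority must be a permutation of the three sources")
    if not records:
        return []
    pid = records[0].patient_id
    if any(r.patient_id != pid for r in records):
        raise ValueError("all records must share one patient_id")

    rank = {s: i for i, s in enumerate(priority)}
    groups: dict[tuple, list[SourceRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        key = rec.identity()
        # a named record also absorbs unnamed records with the same
        # ingredient multiset (and vice versa)
        if key[0] == "name":
            alt = ("ingredients", tuple(sorted(i for i, _ in rec.ingredients)))
            if rec.ingredients and alt in groups and key not in groups:
                groups[key] = groups.pop(alt)
                order[order.index(alt)] = key
        else:
            named = next(
                (
                    k for k in groups
                    if k[0] == "name"
                    and any(g.ingredients and key[1]
                            == tuple(sorted(i for i, _ in g.ingredients))
                            for g in groups[k])
                ),
                None,
            )
            if named is not None:
                key = named
        groups.setdefault(key, [])
        if key not in order:
            order.append(key)
        groups[key].append(rec)

    merged: list[ReconciledMedication] = []
    for key in order:
        grp = sorted(groups[key], key=lambda r: rank[r.source])
        prov: dict[str, str] = {}
        conflicts: set[str] = set()

        def pick(attr: str):
            for rec in grp:
                value = getattr(rec, attr)
                if value not in (None, "", ()):
                    prov[attr] = rec.source.value
                    return value
            return None

        product_name = pick("product_name")
        dosage_form = pick("dosage_form")
        times = pick("administration_times")

        comp_strength: dict[IngredientKey, StrengthSpec | None] = {}
        comp_order: list[IngredientKey] = []
        for rec in grp:
            for ing, st in rec.ingredients:
                if ing not in comp_strength:
                    comp_strength[ing] = None
                    comp_order.append(ing)
                    prov.setdefault("ingredients", rec.source.value)
                if st is not None:
                    if comp_strength[ing] is None:
                        comp_strength[ing] = st
                        prov[f"strength:{ing}"] = rec.source.value
                    elif comp_strength[ing] != st:
                        conflicts.add(f"strength:{ing}")

        top = grp[0]
        merged.append(
            ReconciledMedication(
                patient_id=pid,
                product_name=product_name,
                components=tuple((i, comp_strength[i]) for i in comp_order),
                dosage_form=dosage_form,
                administration_times=times,
                prescribed_during_stay=top.prescribed_during_stay,
                self_medication=top.self_medication,
                provenance=prov,
                conflicts=tuple(sorted(conflicts)),
            )
        )
    return merged


def _filled_fields(rec: SourceRecord) -> int:
    n = sum(
        1
        for v in (rec.product_name, rec.dosage_form, rec.administration_times)
        if v
    )
    if rec.ingredients:
        n += 1
        n += sum(1 for _, st in rec.ingredients if st is not None)
    return n


def classify_main_source(
    records: Sequence[SourceRecord],
    priority: Sequence[Source] = DEFAULT_PRIORITY,
) -> Source:
    """The source contributing the most filled fields for one patient;
    ties go to the higher-priority source."""
    if not records:
        raise ValueError("no records")
    counts = {s: 0 for s in Source}
    for rec in records:
        counts[rec.source] += _filled_fields(rec)
    return max(priority, key=lambda s: (counts[s], -list(priority).index(s)))


# --------------------------------------------------------------------------
# CSV interfaces

def _parse_med_components(text: str) -> tuple[MedComponent, ...]:
    """``ingredient[|salt][:amount unit]`` semicolon-joined; the strength
    part may be absent (unknown)."""
    comps: list[MedComponent] = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            keypart, strength = part.split(":", 1)
            st: StrengthSpec | None = StrengthSpec.parse(strength)
        else:
            keypart, st = part, None
        if "|" in keypart:
            name, salt = keypart.split("|", 1)
        else:
            name, salt = keypart, None
        comps.append((IngredientKey.make(name, salt), st))
    return tuple(comps)


def _format_med_components(components: Iterable[MedComponent]) -> str:
    out = []
    for ing, st in components:
        key = f"{ing.name}|{ing.salt}" if ing.salt else ing.name
        out.append(f"{key}:{st.amount} {st.unit}" if st is not None else key)
    return ";".join(out)


def load_sources(path: str | Path) -> dict[str, list[SourceRecord]]:
    """Read a ``sources.csv`` and return records grouped by patient."""
    schema = load_schema("sources")
    out: dict[str, list[SourceRecord]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            validate_row(schema, row, file=str(path), line=lineno)
            rec = SourceRecord(
                patient_id=row["patient_id"],
                source=Source(row["source"]),
                product_name=row.get("product_name") or None,
                ingredients=_parse_med_components(row.get("ingredients") or ""),
                dosage_form=(row.get("dosage_form") or "").lower() or None,
                administration_times=row.get("administration_times") or None,
                prescribed_during_stay=row.get("prescribed_during_stay", "true") != "false",
                self_medication=row.get("self_medication", "false") == "true",
            )
            out.setdefault(rec.patient_id, []).append(rec)
    return out


def load_cohort(cohort_dir: str | Path) -> list[Patient]:
    """Read ``patients.csv`` + ``medications.csv`` from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    patients: dict[str, Patient] = {}
    pschema = load_schema("patients")
    with (cohort_dir / "patients.csv").open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            validate_row(pschema, row, file="patients.csv", line=lineno)
            p = Patient(
                patient_id=row["patient_id"],
                age=int(row["age"]),
                department=row.get("department", ""),
                main_source=Source(row["main_source"]) if row.get("main_source") else None,
            )
            if p.patient_id in patients:
                raise KBError(f"duplicate patient_id {p.patient_id!r}")
            patients[p.patient_id] = p

    mschema = load_schema("medications")
    with (cohort_dir / "medications.csv").open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            validate_row(mschema, row, file="medications.csv", line=lineno)
            pid = row["patient_id"]
            if pid not in patients:
                raise KBError(f"medications.csv:{lineno}: unknown patient {pid!r}")
            prov = dict(
                item.split("=", 1)
                for item in (row.get("provenance") or "").split(";")
                if "=" in item
            )
            patients[pid].medications.append(
                ReconciledMedication(
                    patient_id=pid,
                    product_name=row.get("product_name") or None,
                    components=_parse_med_components(row.get("components") or ""),
                    dosage_form=(row.get("dosage_form") or "").lower() or None,
                    administration_times=row.get("administration_times") or None,
                    prescribed_during_stay=row.get("prescribed_during_stay", "true") != "false",
                    self_medication=row.get("self_medication", "false") == "true",
                    provenance=prov,
                    conflicts=tuple(
                        c for c in (row.get("conflicts") or "").split(";") if c
                    ),
                )
            )
    return sorted(patients.values(), key=lambda p: p.patient_id)


def save_cohort(patients: Sequence[Patient], cohort_dir: str | Path) -> None:
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    with (cohort_dir / "patients.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "age", "department", "main_source"])
        for p in patients:
            w.writerow([p.patient_id, p.age, p.department,
                        p.main_source.value if p.main_source else ""])
    with (cohort_dir / "medications.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "product_name", "components", "dosage_form",
                    "administration_times", "prescribed_during_stay",
                    "self_medication", "provenance", "conflicts"])
        for p in patients:
            for m in p.medications:
                w.writerow([
                    p.patient_id,
                    m.product_name or "",
                    _format_med_components(m.components),
                    m.dosage_form or "",
                    m.administration_times or "",
                    "true" if m.prescribed_during_stay else "false",
                    "true" if m.self_medication else "false",
                    ";".join(f"{k}={v}" for k, v in sorted(m.provenance.items())),
                    ";".join(m.conflicts),
                ])
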
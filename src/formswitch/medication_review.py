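"""Pre-switch medication review: DDI and PIM screening.

Before any formulary switching, the reconciled medication list is
reviewed for drug-related problems.  Two screens are implemented:

* **drug-drug interactions** -- every unordered pair of distinct active
  ingredients a patient takes concomitantly (combination products
  contribute each component) is looked up in the interaction table.
  Patients with fewer than two concomitant medications are *not
  assessable* and excluded from the denominator.
* **potentially inappropriate medication** -- for patients at or above
  the age threshold (default 65 years), any ingredient that is
  PRISCUS-listed or graded FORTA C/D yields a finding.

Findings are reported, never auto-applied; deprescribing decisions stay
with the clinicians.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from .knowledge_base import InteractionKB, KnowledgeBase, PIMCatalog
from .reconciliation import Patient, ReconciledMedication

__all__ = [
    "DDIFinding",
    "PIMFinding",
    "ReviewSummary",
    "concomitant_pairs",
    "screen_ddi",
    "screen_pim",
    "review_report",
]


@dataclass(frozen=True)
class DDIFinding:
    patient_id: str
    pair: tuple[str, str]  # ingredient names, sorted
    severity: str
    medications: tuple[str, ...]  # display names of the contributing meds


@dataclass(frozen=True)
class PIMFinding:
    patient_id: str
    ingredient: str
    catalog: str  # "PRISCUS" or "FORTA"
    category: str  # "listed" or the FORTA grade


def concomitant_pairs(
    meds: Sequence[ReconciledMedication],
) -> list[tuple[str, str]]:
    """All unordered pairs of distinct ingredient names across the
    medications prescribed during the stay (salts ignored: interactions
    concern the moiety)."""
    carriers: dict[str, list[str]] = {}
    for med in meds:
        if not med.prescribed_during_stay:
            continue
        for ing in med.ingredient_keys():
            carriers.setdefault(ing.name, []).append(med.display_name())
    names = sorted(carriers)
    return [tuple(pair) for pair in itertools.combinations(names, 2)]


def is_assessable(patient: Patient) -> bool:
    """DDI screening needs at least two concomitant medications."""
    return sum(1 for m in patient.medications if m.prescribed_during_stay) >= 2


def screen_ddi(patient: Patient, kb: InteractionKB) -> list[DDIFinding]:
    """Interaction findings: exactly the concomitant pairs present in the
    knowledge base.  Empty for non-assessable patients."""
    if not is_assessable(patient):
        return []
    carriers: dict[str, list[str]] = {}
    for med in patient.medications:
        if not med.prescribed_during_stay:
            continue
        for ing in med.ingredient_keys():
            carriers.setdefault(ing.name, []).append(med.display_name())
    findings = []
    for a, b in concomitant_pairs(patient.medications):
        severity = kb.lookup(a, b)
        if severity is not None:
            findings.append(
                DDIFinding(
                    patient_id=patient.patient_id,
                    pair=(a, b),
                    severity=severity,
                    medications=tuple(dict.fromkeys(carriers[a] + carriers[b])),
                )
            )
    return findings


def screen_pim(
    patient: Patient, catalog: PIMCatalog, age_threshold: int = 65
) -> list[PIMFinding]:
    """PIM findings for patients aged ``age_threshold`` or older; one
    finding per distinct PIM-positive ingredient."""
    if patient.age < age_threshold:
        return []
    seen: set[str] = set()
    findings = []
    for med in patient.medications:
        for ing in med.ingredient_keys():
            if ing.name in seen:
                continue
            seen.add(ing.name)
            hit = catalog.classify(ing)
            if hit is not None:
                findings.append(
                    PIMFinding(patient.patient_id, ing.name, hit[0], hit[1])
                )
    return sorted(findings, key=lambda f: f.ingredient)


@dataclass(frozen=True)
class ReviewSummary:
    n_patients: int
    assessable: int  # patients with >=2 concomitant medications
    with_ddi: int
    aged_65_plus: int
    with_pim: int
    #: ingredients most often involved in interactions, with counts
    top_interacting: tuple[tuple[str, int], ...]
    ddi_findings: tuple[DDIFinding, ...]
    pim_findings: tuple[PIMFinding, ...]


def review_report(
    cohort: Sequence[Patient],
    kb: KnowledgeBase,
    age_threshold: int = 65,
) -> ReviewSummary:
    """Cohort-level review: per-patient screens plus the aggregate rates
    the two screens are judged by (DDI over assessable patients, PIM over
    patients aged 65+)."""
    ddi_all: list[DDIFinding] = []
    pim_all: list[PIMFinding] = []
    assessable = with_ddi = aged = with_pim = 0
    involvement: dict[str, int] = {}
    for patient in cohort:
        if is_assessable(patient):
            assessable += 1
            findings = screen_ddi(patient, kb.interactions)
            ddi_all.extend(findings)
            if findings:
                with_ddi += 1
            for f in findings:
                for name in f.pair:
                    involvement[name] = involvement.get(name, 0) + 1
        if patient.age >= age_threshold:
            aged += 1
            findings_p = screen_pim(patient, kb.pim, age_threshold)
            pim_all.extend(findings_p)
            if findings_p:
                with_pim += 1
    # ties broken alphabetically
    top = sorted(involvement.items(), key=lambda kv: (-kv[1], kv[0]))
    return ReviewSummary(
        n_patients=len(cohort),
        assessable=assessable,
        with_ddi=with_ddi,
        aged_65_plus=aged,
        with_pim=with_pim,
        top_interacting=tuple(top[:5]),
        ddi_findings=tuple(ddi_all),
        pim_findings=tuple(pim_all),
    )
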
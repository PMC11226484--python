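"""The six-step formulary switching cascade (S0-S5) with entry gates.

Every reconciled medication first passes the **gates**, in fixed order:
not prescribed during the stay -> self-medication -> product name unknown
-> strength unknown.  The first gate that fires terminates processing for
that medication (it cannot or need not be switched).  Eligible
medications then walk the cascade and stop at the first matching step:

* **S0** -- the exact product is on the formulary: no switch needed,
  deliver from pharmacy stock.
* **S1** -- an ingredient is on the substitution-exclusion list:
  switching is not allowed; the original product is procured on special
  request countersigned by a senior physician.
* **S2** -- aut idem: a formulary product with the identical ingredient,
  salt, strength and dosage-form class exists (a generic).  Combination
  products prefer a combination-for-combination generic and otherwise a
  full decomposition into mono-products (all-or-nothing); either way the
  combination counts as one switch.
* **S3** -- aut simile: an explicit dose-equivalence table entry maps the
  medication to a therapeutically equivalent formulary product.
* **S4** -- patient-individual switching: only ever driven by an explicit
  pharmacist override entry, never auto-derived.
* **S5** -- nothing matched: the original product is ordered from the
  wholesaler (the costly outcome the algorithm minimizes).

S0 precedes S1 deliberately: an exclusion-listed drug whose exact product
is stocked needs no switch, hence carries no switching risk.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .knowledge_base import (
    Formulary,
    KBError,
    KnowledgeBase,
    Product,
    find_equivalence_candidates,
    find_generic_candidates,
)
from .reconciliation import (
    Completeness,
    Patient,
    ReconciledMedication,
    completeness_status,
)

__all__ = [
    "Status",
    "Channel",
    "SwitchDecision",
    "OverrideEntry",
    "ELIGIBLE",
    "gate",
    "classify_switch",
    "decide",
    "decide_cohort",
    "decompose_combination",
    "build_order_list",
    "OrderLine",
    "OrderList",
]


class Status(str, enum.Enum):
    NOT_PRESCRIBED = "NOT_PRESCRIBED"
    SELF_MEDICATION = "SELF_MEDICATION"
    MISSING_PRODUCT = "MISSING_PRODUCT"
    MISSING_STRENGTH = "MISSING_STRENGTH"
    S0 = "S0"
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    S5 = "S5"


GATE_STATUSES = (
    Status.NOT_PRESCRIBED,
    Status.SELF_MEDICATION,
    Status.MISSING_PRODUCT,
    Status.MISSING_STRENGTH,
)
STEP_STATUSES = (Status.S0, Status.S1, Status.S2, Status.S3, Status.S4, Status.S5)


class Channel(str, enum.Enum):
    STOCK = "stock"
    SPECIAL_REQUEST = "special_request"
    WHOLESALER = "wholesaler"
    NONE = "none"


#: order channel implied by each terminal status
CHANNEL_BY_STATUS: Mapping[Status, Channel] = {
    Status.S0: Channel.STOCK,
    Status.S1: Channel.SPECIAL_REQUEST,
    Status.S2: Channel.STOCK,
    Status.S3: Channel.STOCK,
    Status.S4: Channel.STOCK,
    Status.S5: Channel.WHOLESALER,
    **{s: Channel.NONE for s in GATE_STATUSES},
}

ELIGIBLE = "ELIGIBLE"


@dataclass(frozen=True)
class SwitchDecision:
    medication: ReconciledMedication
    status: Status
    targets: tuple[Product, ...] = ()
    rationale: str = ""

    @property
    def channel(self) -> Channel:
        return CHANNEL_BY_STATUS[self.status]


@dataclass(frozen=True)
class OverrideEntry:
    """A pharmacist's explicit patient-individual switching decision."""

    patient_id: str
    medication: str  # product name, or "ing1/ing2" ingredient identity
    target_product: str
    note: str = ""

    def matches(self, med: ReconciledMedication) -> bool:
        if med.patient_id != self.patient_id:
            return False
        wanted = self.medication.strip().lower()
        if med.product_name and med.product_name.strip().lower() == wanted:
            return True
        return med.display_name().strip().lower() == wanted


def gate(med: ReconciledMedication) -> Status | str:
    """First applicable gate, or ELIGIBLE.  Evaluation order is fixed:
    NOT_PRESCRIBED -> SELF_MEDICATION -> MISSING_PRODUCT -> MISSING_STRENGTH."""
    if not med.prescribed_during_stay:
        return Status.NOT_PRESCRIBED
    if med.self_medication:
        return Status.SELF_MEDICATION
    completeness = completeness_status(med)
    if completeness is Completeness.MISSING_PRODUCT:
        return Status.MISSING_PRODUCT
    if completeness is Completeness.MISSING_STRENGTH:
        return Status.MISSING_STRENGTH
    return ELIGIBLE


def _formulary_match(med: ReconciledMedication, kb: KnowledgeBase) -> Product | None:
    """S0 predicate: the medication's own product, by name, with agreeing
    components and dosage-form class, is stocked."""
    if not med.product_name:
        return None
    product = kb.formulary.get(med.product_name)
    if product is None:
        return None
    if product.component_set() != frozenset(med.components):
        return None
    if kb.form_class(product.dosage_form) != kb.form_class(med.dosage_form or ""):
        return None
    return product


def decompose_combination(
    med: ReconciledMedication, formulary: Formulary,
    form_classes: Mapping[str, str] | None = None,
) -> tuple[Product, ...] | None:
    """S2 resolution for combination products.

    Preference order: (1) a combination-for-combination generic; (2) full
    decomposition, i.e. *every* component has a mono-product at the exact
    strength and dosage-form class -- returned as multiple targets but
    counted as one switch.  Partial decomposition fails (returns None).
    """
    combo_generics = find_generic_candidates(med, formulary, form_classes)
    if combo_generics:
        return (combo_generics[0],)

    classes = form_classes or {}

    def fc(form: str) -> str:
        return classes.get(form.strip().lower(), form.strip().lower())

    med_form = fc(med.dosage_form or "")
    targets = []
    for ing, st in med.components:
        monos = [
            p
            for p in formulary.with_ingredient_names(frozenset((ing.name,)))
            if not p.is_combination
            and p.components[0] == (ing, st)
            and fc(p.dosage_form) == med_form
        ]
        if not monos:
            return None  # all-or-nothing
        targets.append(monos[0])
    return tuple(targets)


def classify_switch(
    med: ReconciledMedication,
    kb: KnowledgeBase,
    overrides: Sequence[OverrideEntry] = (),
) -> SwitchDecision:
    """Walk S0..S5 in strict order and return the first matching step.

    Precondition: ``gate(med)`` is ELIGIBLE.
    """
    if gate(med) is not ELIGIBLE:
        raise ValueError(
            f"medication {med.display_name()!r} is not eligible for switching"
        )

    # S0 - exact product stocked
    product = _formulary_match(med, kb)
    if product is not None:
        return SwitchDecision(
            med, Status.S0, (product,),
            rationale=f"product '{product.product_name}' is listed in the "
                      "hospital formulary; no switching required",
        )

    # S1 - substitution-exclusion list
    excluded = [ing for ing in med.ingredient_keys() if kb.exclusion.covers(ing)]
    if excluded:
        return SwitchDecision(
            med, Status.S1,
            rationale="switching not allowed: "
                      + ", ".join(str(i) for i in excluded)
                      + " on the substitution-exclusion list; order on "
                        "special request (senior physician signature)",
        )

    # S2 - aut idem (generic)
    if med.is_combination:
        targets = decompose_combination(med, kb.formulary, kb.form_classes)
        if targets is not None:
            kind = ("combination generic" if len(targets) == 1
                    else "full decomposition into mono-products")
            return SwitchDecision(
                med, Status.S2, targets,
                rationale=f"generic switching ({kind}); counted as one switch",
            )
    else:
        generics = find_generic_candidates(med, kb.formulary, kb.form_classes)
        if generics:
            names = ", ".join(p.product_name for p in generics)
            return SwitchDecision(
                med, Status.S2, (generics[0],),
                rationale=f"generic switching (aut idem); candidates: {names}",
            )

    # S3 - aut simile via equivalence tables
    equivalents = find_equivalence_candidates(
        med, kb.equivalence, kb.formulary, kb.form_classes
    )
    if equivalents:
        entry, product = equivalents[0]
        return SwitchDecision(
            med, Status.S3, (product,),
            rationale=f"therapeutically equivalent switch per table "
                      f"'{entry.table_id}': {entry.source[0]} "
                      f"{entry.source[1]} -> {entry.target[0]} "
                      f"{entry.target[1]}",
        )

    # S4 - pharmacist override only, never auto-derived
    for entry in overrides:
        if entry.matches(med):
            target = kb.formulary.get(entry.target_product)
            if target is None:
                raise KBError(
                    f"override target {entry.target_product!r} is not in the "
                    "formulary"
                )
            return SwitchDecision(
                med, Status.S4, (target,),
                rationale=f"patient-individual switch by pharmacist: "
                          f"{entry.note or 'no note'}",
            )

    # S5 - nothing worked
    return SwitchDecision(
        med, Status.S5,
        rationale="no standardized or patient-individual switch possible; "
                  "order from wholesaler",
    )


def decide(
    med: ReconciledMedication,
    kb: KnowledgeBase,
    overrides: Sequence[OverrideEntry] = (),
) -> SwitchDecision:
    """Gate first, then cascade: exactly one status per medication."""
    status = gate(med)
    if status is not ELIGIBLE:
        reasons = {
            Status.NOT_PRESCRIBED: "not prescribed during the hospital stay",
            Status.SELF_MEDICATION: "self-medication is not transferred",
            Status.MISSING_PRODUCT: "product name unknown; algorithm not applicable",
            Status.MISSING_STRENGTH: "strength unknown; algorithm not applicable",
        }
        return SwitchDecision(med, status, rationale=reasons[status])
    return classify_switch(med, kb, overrides)


def decide_cohort(
    cohort: Sequence[Patient],
    kb: KnowledgeBase,
    overrides: Sequence[OverrideEntry] = (),
) -> list[SwitchDecision]:
    return [
        decide(med, kb, overrides)
        for patient in cohort
        for med in patient.medications
    ]


# --------------------------------------------------------------------------
# order lists

@dataclass(frozen=True)
class OrderLine:
    product_name: str
    quantity: int
    patient_ids: tuple[str, ...]


@dataclass(frozen=True)
class OrderList:
    #: channel -> aggregated lines, sorted by product name
    groups: Mapping[str, tuple[OrderLine, ...]]
    #: gate-status medications needing information completion first
    pending: tuple[SwitchDecision, ...]


def build_order_list(decisions: Sequence[SwitchDecision]) -> OrderList:
    """Aggregate decisions into per-channel order lines.

    S0/S2/S3/S4 order their target products from stock; S1 orders the
    original product on special request; S5 orders the original product
    from the wholesaler.  Gate-status records are listed separately as
    requiring information completion.
    """
    buckets: dict[str, dict[str, list[str]]] = {
        Channel.STOCK.value: {},
        Channel.SPECIAL_REQUEST.value: {},
        Channel.WHOLESALER.value: {},
    }
    pending: list[SwitchDecision] = []
    for d in decisions:
        if d.channel is Channel.NONE:
            pending.append(d)
            continue
        if d.targets:
            names = [p.product_name for p in d.targets]
        else:
            names = [d.medication.display_name()]
        for name in names:
            buckets[d.channel.value].setdefault(name, []).append(
                d.medication.patient_id
            )
    groups = {
        channel: tuple(
            OrderLine(name, len(pids), tuple(pids))
            for name, pids in sorted(by_name.items())
        )
        for channel, by_name in buckets.items()
    }
    return OrderList(groups=groups, pending=tuple(pending))
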
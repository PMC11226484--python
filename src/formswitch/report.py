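"""Summary statistics and pipeline orchestration.

Reporting conventions follow the study style throughout:

* distributions are summarized as median with 25%/75% quartiles,
  computed by linear interpolation between order statistics (the common
  "type 7" rule);
* percentages are rounded half-up; switching-step percentages use one
  decimal over *all* medications (gate statuses share the denominator),
  review rates are integer percentages over their own denominators (DDI
  over assessable patients, PIM over patients aged 65+).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .knowledge_base import KnowledgeBase, load_knowledge_base
from .medication_review import ReviewSummary, review_report
from .reconciliation import Patient, Source, load_cohort
from .switching_engine import (
    GATE_STATUSES,
    STEP_STATUSES,
    OverrideEntry,
    Status,
    SwitchDecision,
    build_order_list,
    decide_cohort,
)

__all__ = [
    "quartiles",
    "round_half_up",
    "percentage",
    "combination_resolution",
    "SummaryReport",
    "summarize",
    "PipelineConfig",
    "run_pipeline",
    "load_overrides",
    "save_overrides",
]

log = logging.getLogger("formswitch")


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q25, median, Q75) by linear interpolation between order statistics."""
    if len(values) == 0:
        raise ValueError("quartiles of an empty list")
    q25, q50, q75 = np.percentile(np.asarray(values, dtype=float),
                                  [25, 50, 75], method="linear")
    return float(q25), float(q50), float(q75)


def round_half_up(x: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def combination_resolution(decision: SwitchDecision) -> str:
    """How a combination-product medication resolves.

    ``"mono"`` -- the patient ends up on mono-products (full decomposition
    or an individual switch to a mono-product); ``"combination"`` -- the
    patient stays on a combination product (the stocked original for S0,
    a combination generic or equivalent for S2/S3, the original ordered
    on special request or from the wholesaler for S1/S5);
    ``"unresolved"`` -- a gate fired, no switching outcome exists.
    """
    if not decision.medication.is_combination:
        raise ValueError("not a combination product")
    if decision.status in GATE_STATUSES:
        return "unresolved"
    if decision.status in (Status.S1, Status.S5, Status.S0):
        return "combination"
    if all(not t.is_combination for t in decision.targets):
        return "mono"
    return "combination"


def _main_source(patient: Patient) -> Source:
    if patient.main_source is not None:
        return patient.main_source
    counts = {s: 0 for s in Source}
    for med in patient.medications:
        for src in med.provenance.values():
            counts[Source(src)] += 1
    order = (Source.INTERVIEW, Source.MEDICATION_LIST, Source.MEDICAL_DOCUMENTS)
    return max(order, key=lambda s: (counts[s], -order.index(s)))


@dataclass(frozen=True)
class SummaryReport:
    n_patients: int
    n_medications: int
    n_active_ingredients: int
    status_counts: Mapping[str, int]
    status_pct: Mapping[str, float]
    meds_per_patient: tuple[float, float, float]
    age_quartiles: tuple[float, float, float]
    main_sources: Mapping[str, int]
    review: Mapping[str, object]
    combinations: Mapping[str, object]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["status_counts"] = dict(self.status_counts)
        d["status_pct"] = dict(self.status_pct)
        d["main_sources"] = dict(self.main_sources)
        d["review"] = dict(self.review)
        d["combinations"] = dict(self.combinations)
        return d


def summarize(
    decisions: Sequence[SwitchDecision],
    cohort: Sequence[Patient],
    review: ReviewSummary,
) -> SummaryReport:
    """Aggregate pipeline outputs into the study-style summary."""
    n_meds = len(decisions)
    status_order = list(STEP_STATUSES) + list(GATE_STATUSES)
    counts = {s.value: 0 for s in status_order}
    for d in decisions:
        counts[d.status.value] += 1
    pct = {k: percentage(v, n_meds) for k, v in counts.items()}

    combos = [d for d in decisions if d.medication.is_combination]
    resolution = {"mono": 0, "combination": 0, "unresolved": 0}
    for d in combos:
        resolution[combination_resolution(d)] += 1
    n_combo = len(combos)

    sources = {s.value: 0 for s in Source}
    for p in cohort:
        sources[_main_source(p).value] += 1

    n_ingredients = sum(
        len(m.components) for p in cohort for m in p.medications
    )

    return SummaryReport(
        n_patients=len(cohort),
        n_medications=n_meds,
        n_active_ingredients=n_ingredients,
        status_counts=counts,
        status_pct=pct,
        meds_per_patient=quartiles([len(p.medications) for p in cohort])
        if cohort else (0.0, 0.0, 0.0),
        age_quartiles=quartiles([p.age for p in cohort])
        if cohort else (0.0, 0.0, 0.0),
        main_sources=sources,
        review={
            "assessable": review.assessable,
            "with_ddi": review.with_ddi,
            "ddi_pct": percentage(review.with_ddi, review.assessable, 0),
            "aged_65_plus": review.aged_65_plus,
            "with_pim": review.with_pim,
            "pim_pct": percentage(review.with_pim, review.aged_65_plus, 0),
            "top_interacting": list(map(list, review.top_interacting)),
        },
        combinations={
            "n": n_combo,
            "mono": resolution["mono"],
            "mono_pct": percentage(resolution["mono"], n_combo, 0),
            "combination": resolution["combination"],
            "combination_pct": percentage(resolution["combination"], n_combo, 0),
            "unresolved": resolution["unresolved"],
        },
    )


def summary_markdown(s: SummaryReport) -> str:
    lines = [
        "# Switching summary",
        "",
        f"Patients: {s.n_patients}; medications: {s.n_medications} "
        f"({s.n_active_ingredients} active ingredients)",
        f"Medications per patient: median {s.meds_per_patient[1]:g} "
        f"(Q25 {s.meds_per_patient[0]:g} / Q75 {s.meds_per_patient[2]:g})",
        f"Age: median {s.age_quartiles[1]:g} "
        f"(Q25 {s.age_quartiles[0]:g} / Q75 {s.age_quartiles[2]:g})",
        "",
        "| status | n | % |",
        "|---|---|---|",
    ]
    for status, n in s.status_counts.items():
        lines.append(f"| {status} | {n} | {s.status_pct[status]} |")
    r = s.review
    c = s.combinations
    lines += [
        "",
        f"DDI: {r['with_ddi']}/{r['assessable']} assessable patients "
        f"({r['ddi_pct']:g}%); PIM: {r['with_pim']}/{r['aged_65_plus']} "
        f"patients aged 65+ ({r['pim_pct']:g}%)",
        f"Combination products: {c['n']}; to mono-products {c['mono']} "
        f"({c['mono_pct']:g}%), stayed on a combination product "
        f"{c['combination']} ({c['combination_pct']:g}%), "
        f"unresolved {c['unresolved']}",
        "",
    ]
    return "\n".join(lines)


# --------------------------------------------------------------------------
# overrides CSV

def load_overrides(path: str | Path) -> list[OverrideEntry]:
    from .schemas import load_schema, validate_row

    schema = load_schema("overrides")
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            validate_row(schema, row, file=str(path), line=lineno)
            out.append(
                OverrideEntry(
                    patient_id=row["patient_id"],
                    medication=row["medication"],
                    target_product=row["target_product"],
                    note=row.get("note", ""),
                )
            )
    return out


def save_overrides(overrides: Sequence[OverrideEntry], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "medication", "target_product", "note"])
        for o in overrides:
            w.writerow([o.patient_id, o.medication, o.target_product, o.note])


# --------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    kb_dir: Path
    cohort_dir: Path
    out_dir: Path
    overrides_path: Path | None = None
    age_threshold: int = 65


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Load KB + cohort, review, switch, and write all artifacts.

    Outputs (all UTF-8, deterministic for identical inputs):
    ``decisions.csv``, ``orders.csv``, ``review_findings.csv``,
    ``review_report.json``, ``summary.json``, ``summary.md``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("loading knowledge base from %s", config.kb_dir)
    kb = load_knowledge_base(config.kb_dir)
    log.info("formulary: %d products, %d equivalence entries",
             len(kb.formulary), len(kb.equivalence))

    log.info("loading cohort from %s", config.cohort_dir)
    cohort = load_cohort(config.cohort_dir)
    n_meds = sum(len(p.medications) for p in cohort)
    log.info("cohort: %d patients, %d medications", len(cohort), n_meds)

    overrides: list[OverrideEntry] = []
    if config.overrides_path:
        overrides = load_overrides(config.overrides_path)
        log.info("loaded %d override entries", len(overrides))

    review = review_report(cohort, kb, config.age_threshold)
    log.info("review: %d/%d patients with DDI, %d/%d with PIM",
             review.with_ddi, review.assessable,
             review.with_pim, review.aged_65_plus)

    decisions = decide_cohort(cohort, kb, overrides)
    log.info("switching: %d decisions", len(decisions))

    with (out / "decisions.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "medication", "status", "targets",
                    "channel", "rationale"])
        for d in decisions:
            w.writerow([
                d.medication.patient_id,
                d.medication.display_name(),
                d.status.value,
                ";".join(t.product_name for t in d.targets),
                d.channel.value,
                d.rationale,
            ])

    orders = build_order_list(decisions)
    with (out / "orders.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "product_name", "quantity", "patient_ids"])
        for channel, lines in orders.groups.items():
            for line in lines:
                w.writerow([channel, line.product_name, line.quantity,
                            ";".join(line.patient_ids)])
        for d in orders.pending:
            w.writerow(["requires_information_completion",
                        d.medication.display_name(), 1,
                        d.medication.patient_id])

    with (out / "review_findings.csv").open("w", newline="",
                                            encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "type", "detail", "severity_or_category",
                    "medications"])
        for f in review.ddi_findings:
            w.writerow([f.patient_id, "ddi", " + ".join(f.pair), f.severity,
                        ";".join(f.medications)])
        for f in review.pim_findings:
            w.writerow([f.patient_id, "pim", f.ingredient,
                        f"{f.catalog}/{f.category}", ""])

    summary = summarize(decisions, cohort, review)
    review_json = {
        "n_patients": review.n_patients,
        "assessable": review.assessable,
        "with_ddi": review.with_ddi,
        "aged_65_plus": review.aged_65_plus,
        "with_pim": review.with_pim,
        "top_interacting": list(map(list, review.top_interacting)),
    }
    (out / "review_report.json").write_text(
        json.dumps(review_json, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (out / "summary.md").write_text(summary_markdown(summary), encoding="utf-8")
    log.info("artifacts written to %s", out)
    return summary
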
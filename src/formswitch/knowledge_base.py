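"""Reference data consulted by the switching algorithm.

A hospital formulary is the closed list of drug products the pharmacy
stocks.  Switching an outpatient medication onto it consults several
knowledge tables:

* the **formulary** itself (products with ingredient+salt, strength,
  dosage form, optional ATC code),
* a **substitution-exclusion list** of narrow-therapeutic-index
  ingredients that must never be switched between products,
* **dose-equivalence tables** naming explicit source->target ingredient
  and strength pairs for therapeutically equivalent ("aut simile")
  switching,
* a pairwise **drug-drug interaction** table, and
* **PIM catalogs** (PRISCUS membership; FORTA grades A-D) for screening
  potentially inappropriate medication in patients aged 65+.

All tables live as UTF-8 CSV files with a header row and are validated
against the JSON schemas shipped under ``formswitch/data/schemas``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .atc import ATCCode, atc_match, parse_atc
from .schemas import load_schema, validate_row

if TYPE_CHECKING:  # avoid a circular import; reconciliation imports us
    from .reconciliation import ReconciledMedication

__all__ = [
    "KBError",
    "IngredientKey",
    "StrengthSpec",
    "Product",
    "Formulary",
    "ExclusionList",
    "EquivalenceEntry",
    "InteractionKB",
    "PIMCatalog",
    "KnowledgeBase",
    "load_knowledge_base",
    "save_knowledge_base",
    "default_kb_dir",
    "find_generic_candidates",
    "find_equivalence_candidates",
]


class KBError(ValueError):
    """Raised for malformed or inconsistent knowledge-base content."""


# --------------------------------------------------------------------------
# ingredient identity

#: International vs national naming differences seen on real medication
#: lists; lookup is symmetric via canonicalisation to the left-hand form.
SYNONYMS: dict[str, str] = {
    "albuterol": "salbutamol",
    "metamizole": "dipyrone",
    "levothyroxine": "l-thyroxine",
    "aspirin": "acetylsalicylic acid",
    "acetaminophen": "paracetamol",
    "ciclosporine": "ciclosporin",
    "cyclosporine": "ciclosporin",
}


def normalize_name(name: str) -> str:
    n = " ".join(name.strip().lower().split())
    return SYNONYMS.get(n, n)


@dataclass(frozen=True, order=True)
class IngredientKey:
    """Identity of an active ingredient, salt-aware.

    Two keys are equal iff name *and* salt agree: metoprolol succinate and
    metoprolol tartrate are distinct switching entities even though the
    base moiety is shared.
    """

    name: str
    salt: str | None = None

    @classmethod
    def make(cls, name: str, salt: str | None = None) -> "IngredientKey":
        return cls(normalize_name(name), normalize_name(salt) if salt else None)

    def __str__(self) -> str:
        return f"{self.name} {self.salt}" if self.salt else self.name


# --------------------------------------------------------------------------
# strengths

# canonical unit and multiplicative factor for each accepted spelling
_UNIT_TABLE: dict[str, tuple[str, Decimal]] = {
    "mg": ("mg", Decimal(1)),
    "g": ("mg", Decimal(1000)),
    "mcg": ("mg", Decimal("0.001")),
    "ug": ("mg", Decimal("0.001")),
    "µg": ("mg", Decimal("0.001")),
    "mg/ml": ("mg/ml", Decimal(1)),
    "g/l": ("mg/ml", Decimal(1)),
    "mcg/ml": ("mg/ml", Decimal("0.001")),
    "iu": ("iu", Decimal(1)),
    "i.u.": ("iu", Decimal(1)),
    "ie": ("iu", Decimal(1)),
    "iu/ml": ("iu/ml", Decimal(1)),
    "ie/ml": ("iu/ml", Decimal(1)),
}

_STRENGTH_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*([^\s0-9]+)\s*$")


@dataclass(frozen=True)
class StrengthSpec:
    """A positive per-component amount with unit.

    Comparison and hashing use the canonical base unit (mass in mg,
    concentrations in mg/ml, international units kept distinct as iu),
    so ``0.1 g == 100 mg`` but ``100 iu != 100 mg``.
    """

    amount: Decimal
    unit: str

    def __post_init__(self) -> None:
        if self.unit.lower() not in _UNIT_TABLE:
            raise KBError(f"unknown strength unit {self.unit!r}")
        if self.amount <= 0:
            raise KBError(f"strength must be positive, got {self.amount}")

    @classmethod
    def parse(cls, text: str) -> "StrengthSpec":
        m = _STRENGTH_RE.match(text)
        if not m:
            raise KBError(f"cannot parse strength {text!r}")
        try:
            amount = Decimal(m.group(1))
        except InvalidOperation as exc:  # pragma: no cover - regex guards
            raise KBError(f"cannot parse strength {text!r}") from exc
        return cls(amount, m.group(2))

    def canonical(self) -> tuple[Decimal, str]:
        base, factor = _UNIT_TABLE[self.unit.lower()]
        return ((self.amount * factor).normalize(), base)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrengthSpec):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __str__(self) -> str:
        return f"{self.amount} {self.unit}"


Component = tuple[IngredientKey, StrengthSpec]


# --------------------------------------------------------------------------
# products and the formulary

@dataclass(frozen=True)
class Product:
    """A named drug product: >=1 (ingredient, strength) components.

    A product with two or more components is a combination product.
    """

    product_name: str
    components: tuple[Component, ...]
    dosage_form: str
    atc: ATCCode | None = None

    def __post_init__(self) -> None:
        if not self.components:
            raise KBError(f"product {self.product_name!r} has no components")
        keys = [ing for ing, _ in self.components]
        if len(set(keys)) != len(keys):
            raise KBError(
                f"product {self.product_name!r} repeats an ingredient key"
            )

    @property
    def is_combination(self) -> bool:
        return len(self.components) >= 2

    def component_set(self) -> frozenset[Component]:
        """Identity used for generic ("aut idem") matching."""
        return frozenset(self.components)

    def ingredient_names(self) -> frozenset[str]:
        return frozenset(ing.name for ing, _ in self.components)


class Formulary:
    """The set of stocked products, unique by product name."""

    def __init__(self, products: Iterable[Product] = ()) -> None:
        self._by_name: dict[str, Product] = {}
        self._by_ingredients: dict[frozenset[str], list[Product]] = {}
        for p in products:
            self.add(p)

    def add(self, product: Product) -> None:
        key = product.product_name.strip().lower()
        if key in self._by_name:
            raise KBError(f"duplicate product_name {product.product_name!r}")
        self._by_name[key] = product
        self._by_ingredients.setdefault(product.ingredient_names(), []).append(
            product
        )

    def with_ingredient_names(self, names: frozenset[str]) -> list[Product]:
        """Products whose ingredient-name set equals ``names`` (salt- and
        strength-insensitive pre-filter), sorted by product name."""
        return sorted(self._by_ingredients.get(names, ()),
                      key=lambda p: p.product_name)

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(sorted(self._by_name.values(), key=lambda p: p.product_name))

    def __contains__(self, product_name: str) -> bool:
        return product_name.strip().lower() in self._by_name

    def get(self, product_name: str) -> Product | None:
        return self._by_name.get(product_name.strip().lower())

    def atc_for_ingredient(self, key: IngredientKey) -> ATCCode | None:
        """ATC code of any mono product of this ingredient, if recorded."""
        for p in self.with_ingredient_names(frozenset((key.name,))):
            if not p.is_combination and p.components[0][0] == key and p.atc:
                return p.atc
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formulary):
            return NotImplemented
        return self._by_name == other._by_name


@dataclass(frozen=True)
class ExclusionList:
    """Ingredients that must never be switched between products (S1).

    Entries without a salt match any salt of the ingredient.
    """

    ingredients: frozenset[IngredientKey]

    def covers(self, key: IngredientKey) -> bool:
        if key in self.ingredients:
            return True
        return IngredientKey(key.name) in self.ingredients


#: The substitution-exclusion ingredients fixed by the hospital's Drug
#: Commission: anticonvulsants and immunosuppressants with critical
#: pharmacokinetics.
DEFAULT_EXCLUSION = ExclusionList(
    frozenset(
        IngredientKey(n)
        for n in (
            "carbamazepine",
            "phenobarbital",
            "phenytoin",
            "primidone",
            "valproic acid",
            "ciclosporin",
            "tacrolimus",
        )
    )
)


@dataclass(frozen=True)
class EquivalenceEntry:
    """One explicit source->target row of a dose-equivalence table."""

    source: Component
    target: Component
    match_level: int
    table_id: str

    def __post_init__(self) -> None:
        if self.source[0] == self.target[0]:
            raise KBError(
                f"equivalence entry maps {self.source[0]} to itself"
            )
        if self.match_level not in (4, 5):
            raise KBError(f"match_level must be 4 or 5, got {self.match_level}")


class InteractionKB:
    """Unordered ingredient pairs with a severity label.

    Interactions concern the active moiety, so lookup ignores salts and
    is symmetric in pair order.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, str]] = ()) -> None:
        self._pairs: dict[frozenset[str], str] = {}
        for a, b, severity in pairs:
            na, nb = normalize_name(a), normalize_name(b)
            if na == nb:
                raise KBError(f"self-interaction for {na!r}")
            self._pairs[frozenset((na, nb))] = severity

    def lookup(self, a: str, b: str) -> str | None:
        return self._pairs.get(frozenset((normalize_name(a), normalize_name(b))))

    def __len__(self) -> int:
        return len(self._pairs)

    def items(self) -> list[tuple[tuple[str, str], str]]:
        return sorted(
            ((tuple(sorted(k)), v) for k, v in self._pairs.items())
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionKB):
            return NotImplemented
        return self._pairs == other._pairs


@dataclass(frozen=True)
class PIMCatalog:
    """PRISCUS membership plus FORTA categories, keyed by ingredient name.

    An ingredient is PIM-positive when it is PRISCUS-listed or graded
    FORTA C or D.
    """

    priscus: frozenset[str] = frozenset()
    forta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.forta.values() if c not in "ABCD" or len(c) != 1}
        if bad:
            raise KBError(f"invalid FORTA categories: {sorted(bad)}")

    def classify(self, key: IngredientKey) -> tuple[str, str] | None:
        """Return (catalog, category) if PIM-positive, else None."""
        name = key.name
        if name in self.priscus:
            return ("PRISCUS", "listed")
        cat = self.forta.get(name)
        if cat in ("C", "D"):
            return ("FORTA", cat)
        return None


@dataclass
class KnowledgeBase:
    """Everything the switching cascade and the review consult."""

    formulary: Formulary
    exclusion: ExclusionList = DEFAULT_EXCLUSION
    equivalence: tuple[EquivalenceEntry, ...] = ()
    interactions: InteractionKB = field(default_factory=InteractionKB)
    pim: PIMCatalog = field(default_factory=PIMCatalog)
    #: optional coarse dosage-form equivalence classes; default = exact
    #: form-token equality
    form_classes: Mapping[str, str] = field(default_factory=dict)

    def form_class(self, form: str) -> str:
        token = form.strip().lower()
        return self.form_classes.get(token, token)


# --------------------------------------------------------------------------
# CSV (de)serialization

_COMPONENT_RE = re.compile(r"^([^|:]+)(?:\|([^:]+))?:(.+)$")


def _parse_components(text: str, where: str) -> tuple[Component, ...]:
    comps: list[Component] = []
    for part in text.split(";"):
        m = _COMPONENT_RE.match(part.strip())
        if not m:
            raise KBError(f"{where}: bad component {part!r} "
                          "(expected 'ingredient[|salt]:amount unit')")
        name, salt, strength = m.groups()
        comps.append((IngredientKey.make(name, salt), StrengthSpec.parse(strength)))
    return tuple(comps)


def _format_components(components: Iterable[Component]) -> str:
    out = []
    for ing, st in components:
        key = f"{ing.name}|{ing.salt}" if ing.salt else ing.name
        out.append(f"{key}:{st.amount} {st.unit}")
    return ";".join(out)


def _read_rows(path: Path, schema_name: str) -> list[dict[str, str]]:
    schema = load_schema(schema_name)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            validate_row(schema, row, file=str(path), line=lineno)
            rows.append(row)
    return rows


def load_formulary(path: Path) -> Formulary:
    formulary = Formulary()
    for i, row in enumerate(_read_rows(path, "formulary"), start=2):
        where = f"{path}:{i}"
        atc = parse_atc(row["atc"]) if row.get("atc") else None
        try:
            formulary.add(
                Product(
                    product_name=row["product_name"].strip(),
                    components=_parse_components(row["components"], where),
                    dosage_form=row["dosage_form"].strip().lower(),
                    atc=atc,
                )
            )
        except KBError as exc:
            raise KBError(f"{where}: {exc}") from exc
    return formulary


def load_knowledge_base(kb_dir: str | Path) -> KnowledgeBase:
    """Load and cross-validate all tables from a KB directory.

    Expects ``formulary.csv``, ``exclusion_list.csv``, ``equivalence.csv``,
    ``interactions.csv`` and ``pim.csv``.  Equivalence entries are checked
    against ATC levels whenever both ingredients have coded mono products
    in the formulary.
    """
    kb_dir = Path(kb_dir)
    for name in ("formulary.csv", "exclusion_list.csv", "equivalence.csv",
                 "interactions.csv", "pim.csv"):
        if not (kb_dir / name).exists():
            raise KBError(f"knowledge base file missing: {kb_dir / name}")

    formulary = load_formulary(kb_dir / "formulary.csv")

    excl = frozenset(
        IngredientKey.make(r["ingredient"], r.get("salt") or None)
        for r in _read_rows(kb_dir / "exclusion_list.csv", "exclusion_list")
    )

    entries: list[EquivalenceEntry] = []
    for i, r in enumerate(_read_rows(kb_dir / "equivalence.csv", "equivalence"),
                          start=2):
        entry = EquivalenceEntry(
            source=(IngredientKey.make(r["source_ingredient"]),
                    StrengthSpec.parse(r["source_strength"])),
            target=(IngredientKey.make(r["target_ingredient"]),
                    StrengthSpec.parse(r["target_strength"])),
            match_level=int(r["match_level"]),
            table_id=r["table_id"].strip(),
        )
        src_atc = formulary.atc_for_ingredient(entry.source[0])
        tgt_atc = formulary.atc_for_ingredient(entry.target[0])
        if (src_atc and tgt_atc
                and min(src_atc.level, tgt_atc.level) >= entry.match_level
                and not atc_match(src_atc, tgt_atc, entry.match_level)):
            raise KBError(
                f"{kb_dir / 'equivalence.csv'}:{i}: {entry.source[0]} and "
                f"{entry.target[0]} do not share ATC level {entry.match_level}"
            )
        entries.append(entry)

    interactions = InteractionKB(
        (r["ingredient_a"], r["ingredient_b"], r["severity"].strip().lower())
        for r in _read_rows(kb_dir / "interactions.csv", "interactions")
    )

    priscus: set[str] = set()
    forta: dict[str, str] = {}
    for r in _read_rows(kb_dir / "pim.csv", "pim"):
        name = normalize_name(r["ingredient"])
        if r["catalog"].strip().lower() == "priscus":
            priscus.add(name)
        else:
            forta[name] = r["category"].strip().upper()

    return KnowledgeBase(
        formulary=formulary,
        exclusion=ExclusionList(excl),
        equivalence=tuple(entries),
        interactions=interactions,
        pim=PIMCatalog(frozenset(priscus), forta),
    )


def save_knowledge_base(kb: KnowledgeBase, kb_dir: str | Path) -> None:
    """Write a KB back to the five-table CSV layout (round-trips with load)."""
    kb_dir = Path(kb_dir)
    kb_dir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, header: list[str], rows: Iterable[list]) -> None:
        with (kb_dir / name).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    _write(
        "formulary.csv",
        ["product_name", "dosage_form", "atc", "components"],
        (
            [p.product_name, p.dosage_form, p.atc.code if p.atc else "",
             _format_components(p.components)]
            for p in kb.formulary
        ),
    )
    _write(
        "exclusion_list.csv",
        ["ingredient", "salt"],
        ([k.name, k.salt or ""] for k in sorted(kb.exclusion.ingredients)),
    )
    _write(
        "equivalence.csv",
        ["table_id", "source_ingredient", "source_strength",
         "target_ingredient", "target_strength", "match_level"],
        (
            [e.table_id, str(e.source[0]), str(e.source[1]),
             str(e.target[0]), str(e.target[1]), e.match_level]
            for e in kb.equivalence
        ),
    )
    _write(
        "interactions.csv",
        ["ingredient_a", "ingredient_b", "severity"],
        ([a, b, sev] for (a, b), sev in kb.interactions.items()),
    )
    pim_rows = [[n, "priscus", "listed"] for n in sorted(kb.pim.priscus)]
    pim_rows += [[n, "forta", c] for n, c in sorted(kb.pim.forta.items())]
    _write("pim.csv", ["ingredient", "catalog", "category"], pim_rows)


def default_kb_dir() -> Path:
    """Directory of the packaged default knowledge base."""
    return Path(__file__).parent / "data" / "default_kb"


# --------------------------------------------------------------------------
# candidate searches

def _known_components(med: "ReconciledMedication") -> tuple[Component, ...]:
    comps = []
    for ing, st in med.components:
        if st is None:
            raise KBError(f"medication {med.display_name()} has unknown strength")
        comps.append((ing, st))
    return tuple(comps)


def find_generic_candidates(
    med: "ReconciledMedication", formulary: Formulary,
    form_classes: Mapping[str, str] | None = None,
) -> list[Product]:
    """Aut-idem candidates: identical component multiset, same dosage-form
    class, different product name.  Ordered by product name (deterministic
    tie-break)."""
    classes = form_classes or {}

    def fc(form: str) -> str:
        return classes.get(form.strip().lower(), form.strip().lower())

    target = frozenset(_known_components(med))
    med_name = (med.product_name or "").strip().lower()
    pool = formulary.with_ingredient_names(
        frozenset(ing.name for ing, _ in med.components)
    )
    out = [
        p
        for p in pool
        if len(p.components) == len(med.components)
        and p.component_set() == target
        and fc(p.dosage_form) == fc(med.dosage_form or "")
        and p.product_name.strip().lower() != med_name
    ]
    return sorted(out, key=lambda p: p.product_name)


def find_equivalence_candidates(
    med: "ReconciledMedication",
    entries: Iterable[EquivalenceEntry],
    formulary: Formulary,
    form_classes: Mapping[str, str] | None = None,
) -> list[tuple[EquivalenceEntry, Product]]:
    """Aut-simile candidates via explicit dose-equivalence entries.

    For a mono medication: entries whose source (ingredient, strength)
    exactly matches the medication, paired with formulary mono products of
    the target ingredient at the equivalent strength and the same
    dosage-form class.  For a combination medication: an entry may convert
    one component; the candidate must be a formulary combination product
    carrying the converted component plus all remaining components at
    identical strengths.

    When both sides have ATC-coded products, agreement at the entry's
    match level is verified (violations were already rejected at load
    time, so this is a belt-and-braces check).
    """
    classes = form_classes or {}

    def fc(form: str) -> str:
        return classes.get(form.strip().lower(), form.strip().lower())

    comps = _known_components(med)
    med_form = fc(med.dosage_form or "")
    results: list[tuple[EquivalenceEntry, Product]] = []
    for entry in entries:
        for idx, comp in enumerate(comps):
            if comp != entry.source:
                continue
            wanted = frozenset(
                [entry.target] + [c for j, c in enumerate(comps) if j != idx]
            )
            pool = formulary.with_ingredient_names(
                frozenset(ing.name for ing, _ in wanted)
            )
            for p in pool:
                if len(p.components) != len(comps):
                    continue
                if p.component_set() != wanted or fc(p.dosage_form) != med_form:
                    continue
                # ATC agreement is only checkable against mono candidates;
                # combination products carry combination codes.
                src_atc = formulary.atc_for_ingredient(entry.source[0])
                if (not p.is_combination and src_atc and p.atc
                        and min(src_atc.level, p.atc.level) >= entry.match_level
                        and not atc_match(src_atc, p.atc, entry.match_level)):
                    continue
                results.append((entry, p))
    return sorted(results, key=lambda ep: (ep[1].product_name, ep[0].table_id))
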
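"""Knowledge-base types, loading/serialization and candidate searches."""

from decimal import Decimal
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from formswitch.knowledge_base import (
    EquivalenceEntry,
    Formulary,
    IngredientKey,
    KBError,
    Product,
    StrengthSpec,
    default_kb_dir,
    find_equivalence_candidates,
    find_generic_candidates,
    load_knowledge_base,
    save_knowledge_base,
)
from formswitch.reconciliation import ReconciledMedication
from formswitch.schemas import SchemaError


def med(product, components, form="tablet", pid="P1"):
    return ReconciledMedication(
        patient_id=pid,
        product_name=product,
        components=tuple(
            (IngredientKey.make(n, s), StrengthSpec.parse(st_))
            for n, s, st_ in components
        ),
        dosage_form=form,
    )


def mono(name, ingredient, strength, form="tablet", salt=None):
    return Product(
        name,
        ((IngredientKey.make(ingredient, salt), StrengthSpec.parse(strength)),),
        form,
    )


# --------------------------------------------------------------------------
# scalar types

class TestStrengthSpec:
    def test_mass_units_normalize_to_mg(self):
        assert StrengthSpec.parse("0.1 g") == StrengthSpec.parse("100 mg")
        assert StrengthSpec.parse("100 mcg") == StrengthSpec.parse("0.1 mg")

    def test_international_units_stay_distinct_from_mass(self):
        assert StrengthSpec.parse("100 iu") != StrengthSpec.parse("100 mg")

    def test_equal_strengths_hash_equal(self):
        assert hash(StrengthSpec.parse("1000 mg")) == hash(
            StrengthSpec(Decimal("1"), "g"))

    @pytest.mark.parametrize("text", ["mg", "-5 mg", "5 parsec", ""])
    def test_rejects_malformed(self, text):
        with pytest.raises(KBError):
            StrengthSpec.parse(text)


class TestIngredientKey:
    def test_salt_is_part_of_identity(self):
        succ = IngredientKey.make("Metoprolol", "Succinate")
        tart = IngredientKey.make("metoprolol", "tartrate")
        assert succ != tart
        assert succ == IngredientKey.make("  metoprolol ", "succinate")

    def test_synonyms_map_to_one_key(self):
        assert IngredientKey.make("Albuterol") == IngredientKey.make("salbutamol")


class TestProduct:
    def test_requires_components(self):
        with pytest.raises(KBError, match="no components"):
            Product("Empty", (), "tablet")

    def test_rejects_repeated_ingredient(self):
        comp = (IngredientKey.make("a"), StrengthSpec.parse("1 mg"))
        with pytest.raises(KBError, match="repeats"):
            Product("Dup", (comp, comp), "tablet")

    def test_combination_flag(self):
        assert not mono("A", "a", "1 mg").is_combination
        combo = Product(
            "AB",
            ((IngredientKey.make("a"), StrengthSpec.parse("1 mg")),
             (IngredientKey.make("b"), StrengthSpec.parse("2 mg"))),
            "tablet",
        )
        assert combo.is_combination


# --------------------------------------------------------------------------
# loading / round trip

def test_default_kb_has_the_seven_exclusion_ingredients():
    kb = load_knowledge_base(default_kb_dir())
    names = {k.name for k in kb.exclusion.ingredients}
    assert names == {
        "carbamazepine", "phenobarbital", "phenytoin", "primidone",
        "valproic acid", "ciclosporin", "tacrolimus",
    }


def test_formulary_rejects_duplicate_product_names():
    f = Formulary([mono("Aspirin 100", "acetylsalicylic acid", "100 mg")])
    with pytest.raises(KBError, match="duplicate product_name"):
        f.add(mono("aspirin 100", "acetylsalicylic acid", "100 mg"))


def test_loader_reports_file_and_row_on_schema_violation(tmp_path):
    src = default_kb_dir()
    for name in ("formulary.csv", "exclusion_list.csv", "equivalence.csv",
                 "interactions.csv", "pim.csv"):
        (tmp_path / name).write_text((src / name).read_text())
    (tmp_path / "pim.csv").write_text(
        "ingredient,catalog,category\ndiazepam,priscus,Z\n")
    with pytest.raises(SchemaError, match=r"pim\.csv:2"):
        load_knowledge_base(tmp_path)


def test_loader_rejects_missing_table(tmp_path):
    with pytest.raises(KBError, match="formulary.csv"):
        load_knowledge_base(tmp_path)


def test_empty_formulary_file_is_a_valid_formulary(tmp_path):
    src = default_kb_dir()
    for name in ("exclusion_list.csv", "equivalence.csv",
                 "interactions.csv", "pim.csv"):
        (tmp_path / name).write_text((src / name).read_text())
    (tmp_path / "formulary.csv").write_text(
        "product_name,dosage_form,atc,components\n")
    # equivalence targets no longer resolvable, but loading must succeed
    kb = load_knowledge_base(tmp_path)
    assert len(kb.formulary) == 0


def test_equivalence_must_respect_atc_levels_when_coded(tmp_path):
    src = default_kb_dir()
    for name in ("formulary.csv", "exclusion_list.csv", "interactions.csv",
                 "pim.csv"):
        (tmp_path / name).write_text((src / name).read_text())
    # metformin (A10BA02) -> rosuvastatin (C10AA07) cannot share level 4
    (tmp_path / "equivalence.csv").write_text(
        "table_id,source_ingredient,source_strength,target_ingredient,"
        "target_strength,match_level\n"
        "bogus,metformin,1000 mg,rosuvastatin,10 mg,4\n")
    with pytest.raises(KBError, match="ATC level 4"):
        load_knowledge_base(tmp_path)


def test_save_load_round_trip_is_identical(tmp_path):
    kb = load_knowledge_base(default_kb_dir())
    save_knowledge_base(kb, tmp_path / "one")
    kb2 = load_knowledge_base(tmp_path / "one")
    save_knowledge_base(kb2, tmp_path / "two")
    for name in ("formulary.csv", "exclusion_list.csv", "equivalence.csv",
                 "interactions.csv", "pim.csv"):
        assert (tmp_path / "one" / name).read_bytes() == \
            (tmp_path / "two" / name).read_bytes(), name
    assert kb2.formulary == kb.formulary
    assert kb2.exclusion == kb.exclusion
    assert kb2.equivalence == kb.equivalence
    assert kb2.interactions == kb.interactions
    assert kb2.pim == kb.pim


# --------------------------------------------------------------------------
# generic candidates (aut idem)

class TestGenericCandidates:
    def test_metoprolol_salts_do_not_cross_match(self):
        formulary = Formulary(
            [mono("Metoprolol Succ Inhouse", "metoprolol", "95 mg",
                  salt="succinate")])
        succ = med("Met Succ Home", [("metoprolol", "succinate", "95 mg")])
        tart = med("Met Tart Home", [("metoprolol", "tartrate", "95 mg")])
        assert [p.product_name for p in
                find_generic_candidates(succ, formulary)] == \
            ["Metoprolol Succ Inhouse"]
        assert find_generic_candidates(tart, formulary) == []

    def test_empty_formulary_yields_no_candidates(self):
        m = med("Aspirin Home", [("acetylsalicylic acid", None, "100 mg")])
        assert find_generic_candidates(m, Formulary()) == []

    def test_same_product_name_is_not_its_own_generic(self):
        formulary = Formulary([mono("Aspirin 100", "acetylsalicylic acid",
                                    "100 mg")])
        m = med("aspirin 100", [("acetylsalicylic acid", None, "100 mg")])
        assert find_generic_candidates(m, formulary) == []

    def test_dosage_form_class_must_match(self):
        formulary = Formulary(
            [mono("Salbutamol Syrup", "salbutamol", "0.1 mg", form="syrup")])
        m = med("Salbutamol Inhaler", [("salbutamol", None, "0.1 mg")],
                form="inhalation")
        assert find_generic_candidates(m, formulary) == []
        merged_forms = {"syrup": "oral-liquid", "inhalation": "oral-liquid"}
        assert len(find_generic_candidates(m, formulary, merged_forms)) == 1

    @given(st.data())
    def test_matches_brute_force_filter_on_random_formularies(self, data):
        """The indexed search equals an exhaustive set-comprehension oracle."""
        ingredients = [f"ing{i}" for i in range(6)]
        strengths = ["5 mg", "10 mg"]
        forms = ["tablet", "capsule"]
        n = data.draw(st.integers(0, 100), label="n_products")
        products = []
        for i in range(n):
            ing = data.draw(st.sampled_from(ingredients))
            products.append(mono(
                f"Prod{i}", ing, data.draw(st.sampled_from(strengths)),
                form=data.draw(st.sampled_from(forms))))
        formulary = Formulary(products)
        m = med("Home", [(data.draw(st.sampled_from(ingredients)), None,
                          data.draw(st.sampled_from(strengths)))],
                form=data.draw(st.sampled_from(forms)))
        expected = sorted(
            (
                p for p in products
                if p.component_set() == frozenset(
                    (ing, s) for ing, s in m.components)
                and p.dosage_form == m.dosage_form
                and p.product_name.lower() != m.product_name.lower()
            ),
            key=lambda p: p.product_name,
        )
        assert find_generic_candidates(m, formulary) == expected


# --------------------------------------------------------------------------
# equivalence candidates (aut simile)

@pytest.fixture
def ppi_setup():
    formulary = Formulary([mono("Pantoprazole Inhouse", "pantoprazole",
                                "40 mg")])
    entry = EquivalenceEntry(
        source=(IngredientKey.make("omeprazole"), StrengthSpec.parse("20 mg")),
        target=(IngredientKey.make("pantoprazole"), StrengthSpec.parse("40 mg")),
        match_level=4,
        table_id="ppi",
    )
    return formulary, (entry,)


class TestEquivalenceCandidates:
    def test_listed_source_dose_maps_to_formulary_target(self, ppi_setup):
        formulary, entries = ppi_setup
        m = med("Omeprazole Home", [("omeprazole", None, "20 mg")])
        results = find_equivalence_candidates(m, entries, formulary)
        assert [(e.table_id, p.product_name) for e, p in results] == \
            [("ppi", "Pantoprazole Inhouse")]

    def test_unlisted_dose_yields_nothing(self, ppi_setup):
        formulary, entries = ppi_setup
        m = med("Omeprazole Home", [("omeprazole", None, "40 mg")])
        assert find_equivalence_candidates(m, entries, formulary) == []

    def test_ingredient_without_table_yields_nothing(self, ppi_setup):
        formulary, _ = ppi_setup
        m = med("Solifenacin Home", [("solifenacin", None, "5 mg")])
        assert find_equivalence_candidates(m, (), formulary) == []

    def test_entry_rejects_self_mapping_and_bad_level(self):
        src = (IngredientKey.make("a"), StrengthSpec.parse("1 mg"))
        with pytest.raises(KBError, match="itself"):
            EquivalenceEntry(src, src, 4, "t")
        tgt = (IngredientKey.make("b"), StrengthSpec.parse("1 mg"))
        with pytest.raises(KBError, match="match_level"):
            EquivalenceEntry(src, tgt, 3, "t")
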
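"""Gates, the S0-S5 cascade, combination handling and order lists."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from formswitch.knowledge_base import (
    DEFAULT_EXCLUSION,
    EquivalenceEntry,
    ExclusionList,
    Formulary,
    IngredientKey,
    KBError,
    KnowledgeBase,
    Product,
    StrengthSpec,
)
from formswitch.reconciliation import ReconciledMedication
from formswitch.switching_engine import (
    Channel,
    ELIGIBLE,
    OverrideEntry,
    Status,
    build_order_list,
    classify_switch,
    decide,
    decide_cohort,
    decompose_combination,
    gate,
)


def med(product, components, form="tablet", pid="P1", prescribed=True,
        self_med=False):
    return ReconciledMedication(
        patient_id=pid,
        product_name=product,
        components=tuple(
            (IngredientKey.make(n, s),
             StrengthSpec.parse(amount) if amount else None)
            for n, s, amount in components
        ),
        dosage_form=form,
        prescribed_during_stay=prescribed,
        self_medication=self_med,
    )


def mono(name, ingredient, strength, form="tablet", salt=None):
    return Product(
        name,
        ((IngredientKey.make(ingredient, salt), StrengthSpec.parse(strength)),),
        form,
    )


def combo(name, comps, form="tablet"):
    return Product(
        name,
        tuple((IngredientKey.make(n), StrengthSpec.parse(s)) for n, s in comps),
        form,
    )


def kb_with(products=(), exclusion=DEFAULT_EXCLUSION, equivalence=()):
    return KnowledgeBase(formulary=Formulary(products), exclusion=exclusion,
                         equivalence=tuple(equivalence))


class TestGate:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(prescribed=False), Status.NOT_PRESCRIBED),
            (dict(prescribed=False, self_med=True), Status.NOT_PRESCRIBED),
            (dict(self_med=True), Status.SELF_MEDICATION),
            (dict(), Status.MISSING_PRODUCT),
        ],
    )
    def test_gate_precedence(self, kwargs, expected):
        m = med(None, [("a", None, "5 mg")], **kwargs)
        assert gate(m) is expected

    def test_missing_strength_and_eligible(self):
        assert gate(med("X Home", [("a", None, None)])) is \
            Status.MISSING_STRENGTH
        assert gate(med("X Home", [("a", None, "5 mg")])) is ELIGIBLE


class TestCascade:
    def test_s0_when_exact_product_is_stocked(self):
        kb = kb_with([mono("Apixaban Inhouse", "apixaban", "5 mg")])
        d = classify_switch(med("Apixaban Inhouse",
                                [("apixaban", None, "5 mg")]), kb)
        assert d.status is Status.S0
        assert d.channel is Channel.STOCK
        assert [t.product_name for t in d.targets] == ["Apixaban Inhouse"]

    def test_s1_for_exclusion_listed_ingredient_even_with_generic(self):
        kb = kb_with([mono("Carbamazepine Inhouse", "carbamazepine",
                           "200 mg")])
        d = classify_switch(med("Tegral Home",
                                [("carbamazepine", None, "200 mg")]), kb)
        assert d.status is Status.S1
        assert d.channel is Channel.SPECIAL_REQUEST
        assert d.targets == ()

    def test_s0_precedes_s1_when_exact_product_stocked(self):
        kb = kb_with([mono("Carbamazepine Inhouse", "carbamazepine",
                           "200 mg")])
        d = classify_switch(med("Carbamazepine Inhouse",
                                [("carbamazepine", None, "200 mg")]), kb)
        assert d.status is Status.S0

    def test_s2_generic_switch_to_stock(self):
        kb = kb_with([mono("ASA Inhouse", "acetylsalicylic acid", "100 mg")])
        d = classify_switch(
            med("ASS Home", [("acetylsalicylic acid", None, "100 mg")]), kb)
        assert d.status is Status.S2
        assert d.channel is Channel.STOCK

    def test_s3_equivalence_switch(self):
        entry = EquivalenceEntry(
            (IngredientKey.make("omeprazole"), StrengthSpec.parse("20 mg")),
            (IngredientKey.make("pantoprazole"), StrengthSpec.parse("40 mg")),
            4, "ppi")
        kb = kb_with([mono("Pantoprazole Inhouse", "pantoprazole", "40 mg")],
                     equivalence=[entry])
        d = classify_switch(med("Omeprazole Home",
                                [("omeprazole", None, "20 mg")]), kb)
        assert d.status is Status.S3
        assert [t.product_name for t in d.targets] == ["Pantoprazole Inhouse"]

    def test_s4_requires_an_override_and_a_stocked_target(self):
        kb = kb_with([mono("Pantoprazole Inhouse", "pantoprazole", "40 mg")])
        m = med("Omeprazole Home", [("omeprazole", None, "10 mg")])
        assert classify_switch(m, kb).status is Status.S5  # no override
        override = OverrideEntry("P1", "Omeprazole Home",
                                 "Pantoprazole Inhouse", "ppi switch")
        d = classify_switch(m, kb, [override])
        assert d.status is Status.S4
        bad = OverrideEntry("P1", "Omeprazole Home", "Nonexistent", "")
        with pytest.raises(KBError, match="Nonexistent"):
            classify_switch(m, kb, [bad])

    def test_s5_when_nothing_matches(self):
        kb = kb_with([mono("Metoprolol Succ Inhouse", "metoprolol", "95 mg",
                           salt="succinate")])
        d = classify_switch(
            med("Met Tart Home", [("metoprolol", "tartrate", "50 mg")]), kb)
        assert d.status is Status.S5
        assert d.channel is Channel.WHOLESALER

    def test_classify_rejects_non_eligible_medication(self):
        with pytest.raises(ValueError, match="not eligible"):
            classify_switch(med(None, [("a", None, "5 mg")]), kb_with())

    @given(st.data())
    def test_matches_brute_force_predicate_oracle(self, data):
        """On random mono medications and knowledge bases, the cascade
        equals independently evaluating all six predicates and taking the
        lowest matching index."""
        ingredients = [f"i{k}" for k in range(5)]
        strengths = ["5 mg", "10 mg"]
        products = []
        for i in range(data.draw(st.integers(0, 12))):
            products.append(mono(f"Prod{i}",
                                 data.draw(st.sampled_from(ingredients)),
                                 data.draw(st.sampled_from(strengths))))
        excl = ExclusionList(frozenset(
            IngredientKey.make(n)
            for n in data.draw(st.lists(st.sampled_from(ingredients),
                                        max_size=2))))
        entries = []
        for _ in range(data.draw(st.integers(0, 3))):
            a, b = data.draw(
                st.tuples(st.sampled_from(ingredients),
                          st.sampled_from(ingredients))
                .filter(lambda x: x[0] != x[1]))
            entries.append(EquivalenceEntry(
                (IngredientKey.make(a), StrengthSpec.parse(
                    data.draw(st.sampled_from(strengths)))),
                (IngredientKey.make(b), StrengthSpec.parse(
                    data.draw(st.sampled_from(strengths)))),
                4, "tbl"))
        kb = KnowledgeBase(formulary=Formulary(products), exclusion=excl,
                           equivalence=tuple(entries))
        name = data.draw(st.sampled_from(
            [f"Prod{i}" for i in range(12)] + ["Home A", "Home B"]))
        m = med(name, [(data.draw(st.sampled_from(ingredients)), None,
                        data.draw(st.sampled_from(strengths)))])
        overrides = []
        if data.draw(st.booleans()) and products:
            overrides.append(OverrideEntry(
                "P1", name, products[0].product_name, ""))

        # independent predicate evaluation
        stocked = next(
            (p for p in products
             if p.product_name.lower() == name.lower()
             and p.component_set() == frozenset(m.components)
             and p.dosage_form == m.dosage_form), None)
        s1 = any(excl.covers(ing) for ing, _ in m.components)
        s2 = any(p.component_set() == frozenset(m.components)
                 and p.product_name.lower() != name.lower()
                 and p.dosage_form == m.dosage_form for p in products)
        s3 = any(
            e.source == m.components[0]
            and any(p.component_set() == frozenset((e.target,))
                    and p.dosage_form == m.dosage_form for p in products)
            for e in entries)
        s4 = bool(overrides)
        if stocked:
            expected = Status.S0
        elif s1:
            expected = Status.S1
        elif s2:
            expected = Status.S2
        elif s3:
            expected = Status.S3
        elif s4:
            expected = Status.S4
        else:
            expected = Status.S5
        assert classify_switch(m, kb, overrides).status is expected


class TestCombinations:
    hct = ("hydrochlorothiazide", "12.5 mg")
    cande = ("candesartan", "16 mg")

    def test_combo_generic_is_preferred_over_decomposition(self):
        formulary = Formulary([
            combo("Cande/HCT Generic", [self.cande, self.hct]),
            mono("Candesartan Inhouse", "candesartan", "16 mg"),
            mono("HCT Inhouse", "hydrochlorothiazide", "12.5 mg"),
        ])
        m = med("Cande/HCT Home", [("candesartan", None, "16 mg"),
                                   ("hydrochlorothiazide", None, "12.5 mg")])
        targets = decompose_combination(m, formulary)
        assert [t.product_name for t in targets] == ["Cande/HCT Generic"]

    def test_full_decomposition_returns_all_mono_targets(self):
        formulary = Formulary([
            mono("Candesartan Inhouse", "candesartan", "16 mg"),
            mono("HCT Inhouse", "hydrochlorothiazide", "12.5 mg"),
        ])
        m = med("Cande/HCT Home", [("candesartan", None, "16 mg"),
                                   ("hydrochlorothiazide", None, "12.5 mg")])
        targets = decompose_combination(m, formulary)
        assert sorted(t.product_name for t in targets) == \
            ["Candesartan Inhouse", "HCT Inhouse"]
        d = classify_switch(m, kb_with(list(formulary)))
        assert d.status is Status.S2
        assert len(d.targets) == 2  # one switch, two order lines

    def test_partial_decomposition_is_all_or_nothing(self):
        formulary = Formulary([
            mono("Candesartan Inhouse", "candesartan", "16 mg"),
        ])
        m = med("Cande/HCT Home", [("candesartan", None, "16 mg"),
                                   ("hydrochlorothiazide", None, "12.5 mg")])
        assert decompose_combination(m, formulary) is None
        assert classify_switch(m, kb_with(list(formulary))).status is Status.S5

    def test_s2_conserves_the_component_multiset(self, paper_decisions):
        for d in paper_decisions:
            if d.status is Status.S2:
                source = frozenset(d.medication.components)
                target = frozenset(
                    c for t in d.targets for c in t.components)
                assert source == target, d.medication.display_name()


class TestCascadeInvariants:
    def test_every_medication_gets_exactly_one_status(self, paper_fixture,
                                                      paper_decisions):
        patients, _, _ = paper_fixture
        assert len(paper_decisions) == sum(
            len(p.medications) for p in patients)
        assert all(d.status in Status for d in paper_decisions)

    def test_cascade_monotonicity_lower_predicates_false(self, paper_fixture,
                                                         paper_decisions):
        """If a decision is Sk, every earlier step predicate is false."""
        _, kb, _ = paper_fixture
        from formswitch.knowledge_base import (
            find_equivalence_candidates,
            find_generic_candidates,
        )
        from formswitch.switching_engine import _formulary_match

        order = [Status.S0, Status.S1, Status.S2, Status.S3, Status.S4,
                 Status.S5]
        for d in paper_decisions:
            if d.status not in order:
                continue
            k = order.index(d.status)
            m = d.medication
            predicates = {
                Status.S0: lambda: _formulary_match(m, kb) is not None,
                Status.S1: lambda: any(kb.exclusion.covers(i)
                                       for i in m.ingredient_keys()),
                Status.S2: lambda: (
                    decompose_combination(m, kb.formulary, kb.form_classes)
                    is not None if m.is_combination
                    else bool(find_generic_candidates(
                        m, kb.formulary, kb.form_classes))),
                Status.S3: lambda: bool(find_equivalence_candidates(
                    m, kb.equivalence, kb.formulary, kb.form_classes)),
            }
            for status in order[:k]:
                if status in predicates:
                    assert not predicates[status](), (
                        f"{m.display_name()} is {d.status} but "
                        f"{status} predicate holds")

    def test_s1_always_exclusion_listed_and_s3_always_from_table(
            self, paper_fixture, paper_decisions):
        _, kb, _ = paper_fixture
        table_targets = {e.target[0].name for e in kb.equivalence}
        for d in paper_decisions:
            if d.status is Status.S1:
                assert any(kb.exclusion.covers(i)
                           for i in d.medication.ingredient_keys())
            if d.status is Status.S3:
                assert any(ing.name in table_targets
                           for t in d.targets for ing, _ in t.components)

    def test_empty_kb_sends_all_eligible_unexcluded_to_s5(self, paper_fixture):
        patients, _, _ = paper_fixture
        bare = KnowledgeBase(formulary=Formulary(),
                             exclusion=DEFAULT_EXCLUSION)
        for d in decide_cohort(patients, bare):
            if d.status in (Status.S0, Status.S2, Status.S3, Status.S4):
                pytest.fail(f"{d.medication.display_name()} -> {d.status}")

    def test_identical_inputs_give_identical_decisions(self, paper_fixture):
        patients, kb, overrides = paper_fixture
        a = decide_cohort(patients, kb, overrides)
        b = decide_cohort(patients, kb, overrides)
        assert [(d.status, tuple(t.product_name for t in d.targets))
                for d in a] == \
            [(d.status, tuple(t.product_name for t in d.targets))
             for d in b]


class TestOrderList:
    def test_channels_group_and_aggregate(self):
        kb = kb_with([mono("ASA Inhouse", "acetylsalicylic acid", "100 mg")])
        meds = [
            med("ASS Home", [("acetylsalicylic acid", None, "100 mg")],
                pid="P1"),
            med("ASS Home", [("acetylsalicylic acid", None, "100 mg")],
                pid="P2"),
            med("Tegral Home", [("carbamazepine", None, "200 mg")], pid="P3"),
            med("Orphan Home", [("orphan", None, "5 mg")], pid="P4"),
            med(None, [("mystery", None, "5 mg")], pid="P5"),
        ]
        orders = build_order_list([decide(m, kb) for m in meds])
        stock = orders.groups["stock"]
        assert [(l.product_name, l.quantity) for l in stock] == \
            [("ASA Inhouse", 2)]
        assert [l.product_name for l in orders.groups["special_request"]] == \
            ["Tegral Home"]
        assert [l.product_name for l in orders.groups["wholesaler"]] == \
            ["Orphan Home"]
        assert [d.status for d in orders.pending] == [Status.MISSING_PRODUCT]

    def test_wholesaler_group_is_exactly_the_s5_records(self, paper_decisions):
        orders = build_order_list(paper_decisions)
        s5_products = sorted(
            {d.medication.display_name() for d in paper_decisions
             if d.status is Status.S5})
        assert sorted({l.product_name
                       for l in orders.groups["wholesaler"]}) == s5_products
        n_s5 = sum(1 for d in paper_decisions if d.status is Status.S5)
        assert sum(l.quantity for l in orders.groups["wholesaler"]) == n_s5
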
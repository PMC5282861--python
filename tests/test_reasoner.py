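"""Reasoner: closure, classification, materialization, consistency."""

import pytest

from epokb.fixtures import (
    SyntheticKBParams,
    concept_id,
    generate_random_kb,
    infer_oracle,
    materialize_oracle,
)
from epokb.kb_core import (
    Concept,
    Disjoint,
    KBValidationError,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
)
from epokb.reasoner import (
    check_consistency,
    classify_defined,
    compute_closure,
    materialize_relations,
)


def _tiny_kb(*edges):
    """KB with bare named concepts and the given subclass edges."""
    kb = KnowledgeBase()
    names = {n for e in edges for n in e}
    for n in sorted(names) or {"a"}:
        kb.add_concept(Concept(id=n, pref_labels=[LangText(n, "en")]))
    for child, parent in edges:
        kb.axioms.append(SubclassOf(child, parent))
    # minimal root wiring so category derivation is well-defined
    kb.sign_root = kb.disorder_root = kb.anatomy_root = sorted(kb.concepts)[0]
    return kb


class TestClosure:
    def test_chain_transitivity(self):
        kb = _tiny_kb(("a", "b"), ("b", "c"))
        closure = compute_closure(kb)
        assert closure.of("a") == {"a", "b", "c"}

    def test_singleton_reflexivity(self):
        kb = KnowledgeBase()
        kb.add_concept(Concept(id="x", pref_labels=[LangText("x", "en")]))
        kb.sign_root = kb.disorder_root = kb.anatomy_root = "x"
        assert compute_closure(kb).of("x") == {"x"}

    def test_cycle_raises(self):
        kb = _tiny_kb(("a", "b"), ("b", "a"))
        with pytest.raises(KBValidationError, match="cycle"):
            compute_closure(kb)

    def test_random_dag_matches_matrix_power_oracle(self):
        kb, _ = generate_random_kb(
            SyntheticKBParams(concept_count=200, seed=7, defined_class_count=0)
        )
        expected, _ = infer_oracle(kb)
        assert compute_closure(kb).ancestors == expected


class TestClassifyDefined:
    def test_ring_of_fire_under_color_doppler_sign(self, mini_kb):
        edges = {(e.child, e.parent) for e in classify_defined(mini_kb)}
        assert (concept_id("ring of fire sign"), concept_id("color Doppler sign")) in edges

    def test_ring_of_fire_under_tubal_pregnancy_sign(self, mini_kb):
        edges = {(e.child, e.parent) for e in classify_defined(mini_kb)}
        assert (concept_id("ring of fire sign"), concept_id("tubal pregnancy sign")) in edges

    def test_sign_without_restrictions_gains_no_parents(self, mini_kb):
        target = concept_id("intact endometrial midline echo")
        assert all(e.child != target for e in classify_defined(mini_kb))

    def test_property_subsumption_in_definitions(self):
        # definition over the parent property matched by a sub-property assertion
        kb = KnowledgeBase()
        for n in ("sign", "s1", "tech", "t1", "dis", "anat", "D"):
            kb.add_concept(Concept(id=n, pref_labels=[LangText(n, "en")],
                                   definitions=[LangText(n + ".", "en")]))
        kb.sign_root, kb.disorder_root, kb.anatomy_root = "sign", "dis", "anat"
        kb.technical_roots = ["tech"]
        kb.axioms += [
            SubclassOf("s1", "sign"),
            SubclassOf("t1", "tech"),
            SubclassOfRestriction("s1", Restriction("requiresMode", "t1")),
        ]
        from epokb.kb_core.model import EquivalentToDefinition, derive_categories

        kb.axioms.append(
            EquivalentToDefinition("D", "sign", (Restriction("requires", "t1"),))
        )
        derive_categories(kb)
        edges = {(e.child, e.parent) for e in classify_defined(kb)}
        assert ("s1", "D") in edges

    def test_monotone_under_added_restriction(self, mini_kb):
        before = {(e.child, e.parent) for e in classify_defined(mini_kb)}
        kb = mini_kb.copy()
        kb.axioms.append(
            SubclassOfRestriction(
                concept_id("tubal ring sign"),
                Restriction("requiresMode", concept_id("color Doppler mode")),
            )
        )
        after = {(e.child, e.parent) for e in classify_defined(kb)}
        assert before <= after
        assert (concept_id("tubal ring sign"), concept_id("color Doppler sign")) in after


class TestMaterialize:
    def test_child_inherits_suggests(self, mini_kb):
        kb = mini_kb.copy()
        child = Concept(
            id="epo:OPPIO_planted", pref_labels=[LangText("planted child sign", "en")],
            definitions=[LangText("A planted specialisation.", "en")], category="sign",
        )
        kb.concepts[child.id] = child
        kb.axioms.append(SubclassOf(child.id, concept_id("ring of fire sign")))
        rels = materialize_relations(kb)
        assert any(
            r.subject == child.id
            and r.property == "suggests"
            and r.object == concept_id("tubal pregnancy")
            and r.provenance == f"inherited_from:{concept_id('ring of fire sign')}"
            for r in rels
        )

    def test_no_restrictions_no_relations(self):
        kb = _tiny_kb(("a", "b"))
        assert materialize_relations(kb) == []

    def test_random_kb_matches_enumeration_oracle(self):
        kb, _ = generate_random_kb(SyntheticKBParams(concept_count=150, seed=11))
        expected = materialize_oracle(kb)
        got = {(r.subject, r.property, r.object) for r in materialize_relations(kb)}
        assert got == expected

    def test_contains_asserted_projection(self, mini_kb, mini_relations):
        asserted = {
            (ax.child, ax.restriction.property, ax.restriction.filler)
            for ax in mini_kb.restriction_axioms()
        }
        got = {(r.subject, r.property, r.object) for r in mini_relations}
        assert asserted <= got

    def test_output_sorted_and_deterministic(self, mini_kb, mini_relations):
        assert mini_relations == sorted(mini_relations)
        assert mini_relations == materialize_relations(mini_kb)

    def test_technical_filler_also_reported_under_requires(self, mini_relations):
        rof = concept_id("ring of fire sign")
        objs = {r.object for r in mini_relations if r.subject == rof and r.property == "requires"}
        assert concept_id("color Doppler mode (2D)") in objs

    def test_idempotent_under_rerun(self, mini_kb, mini_closure):
        r1 = materialize_relations(mini_kb, mini_closure)
        r2 = materialize_relations(mini_kb, mini_closure)
        assert r1 == r2


class TestConsistency:
    def test_mini_epo_consistent(self, mini_kb, mini_closure):
        assert check_consistency(mini_kb, mini_closure).consistent

    def test_planted_violation_detected(self, mini_kb):
        kb = mini_kb.copy()
        bad = Concept(
            id="epo:OPPIO_badprg", pref_labels=[LangText("impossible pregnancy", "en")],
            definitions=[LangText("Planted inconsistency.", "en")], category="disorder",
        )
        kb.concepts[bad.id] = bad
        kb.axioms += [
            SubclassOf(bad.id, concept_id("tubal pregnancy")),
            SubclassOf(bad.id, concept_id("cervical pregnancy")),
        ]
        report = check_consistency(kb)
        offenders = {v[0] for v in report.violations}
        assert offenders == {bad.id}
        assert len(report.violations) == 1

    def test_disjoint_without_common_descendant_is_clean(self):
        kb = _tiny_kb(("a", "root"), ("b", "root"))
        kb.axioms.append(Disjoint(frozenset({"a", "b"})))
        assert check_consistency(kb).consistent


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_random_kbs(seed):
    """Spot-check sample of the full 1000-trial acceptance sweep."""
    n = 15 + seed * 15
    kb, truth = generate_random_kb(SyntheticKBParams(concept_count=n, seed=seed))
    closure = compute_closure(kb)
    assert closure.ancestors == truth.ancestors
    assert {(e.child, e.parent) for e in classify_defined(kb)} == set(truth.defined_edges)
    got = {(r.subject, r.property, r.object) for r in materialize_relations(kb, closure)}
    assert got == set(truth.relations)


def test_closure_is_partial_order_on_random_kbs():
    for seed in range(8):
        kb, _ = generate_random_kb(SyntheticKBParams(concept_count=70, seed=100 + seed))
        anc = compute_closure(kb).ancestors
        for c, ancestors in anc.items():
            assert c in ancestors  # reflexive
            for a in ancestors:
                assert anc[a] <= ancestors  # transitive
                if a != c:
                    assert c not in anc[a]  # antisymmetric
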
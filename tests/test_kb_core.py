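"""kb_core: model, serialization round-trips, validation, search."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epokb.fixtures import (
    SyntheticKBParams,
    build_mini_epo,
    concept_id,
    generate_random_kb,
)
from epokb.kb_core import (
    Concept,
    KBError,
    KBValidationError,
    KnowledgeBase,
    LangText,
    SubclassOf,
    kb_equal,
    load_kb,
    save_kb,
    search_terms,
    validate_kb,
)
from epokb.kb_core.turtle_io import TurtleSubsetWarning
from epokb.reasoner import compute_closure

RING_OF_FIRE = concept_id("ring of fire sign")


class TestLoadSave:
    def test_mini_epo_json_contains_ring_of_fire(self, tmp_path, mini_kb):
        path = tmp_path / "kb.json"
        save_kb(mini_kb, path)
        kb = load_kb(path)
        assert kb.concepts[RING_OF_FIRE].pref_label("en") == "ring of fire sign"

    def test_empty_kb_with_declared_roots_fails_validation(self, tmp_path):
        kb = KnowledgeBase(sign_root="epo:missing", disorder_root="epo:missing2",
                           anatomy_root="epo:missing3")
        issues = validate_kb(kb)
        assert any("sign_root" in i for i in issues)

    def test_random_kb_json_round_trip(self, tmp_path):
        kb, _ = generate_random_kb(SyntheticKBParams(concept_count=60, seed=1))
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        assert kb_equal(kb, load_kb(path))

    def test_json_save_is_deterministic(self, tmp_path, mini_kb):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_kb(mini_kb, p1)
        save_kb(load_kb(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_parse_failure_reports_line(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json", encoding="utf-8")
        with pytest.raises(KBError, match="line"):
            load_kb(bad)

    def test_load_rejects_dangling_reference(self, tmp_path, mini_kb):
        kb = mini_kb.copy()
        kb.axioms.append(SubclassOf(RING_OF_FIRE, "epo:OPPIO_nowhere"))
        path = tmp_path / "kb.json"
        save_kb(kb, path)
        with pytest.raises(KBValidationError, match="unknown concept"):
            load_kb(path)


class TestTurtle:
    def test_export_contains_restriction_node(self, tmp_path, mini_kb):
        path = tmp_path / "kb.ttl"
        save_kb(mini_kb, path)
        text = path.read_text(encoding="utf-8")
        assert "owl:Restriction" in text
        assert "owl:onProperty epo:requiresMode" in text

    def test_round_trip_preserves_closure(self, tmp_path, mini_kb, mini_closure):
        path = tmp_path / "kb.ttl"
        save_kb(mini_kb, path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            kb2 = load_kb(path)
        closure2 = compute_closure(kb2)
        assert mini_closure.ancestors == closure2.ancestors

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_random_kb_turtle_round_trip_closure_equivalent(self, tmp_path, seed):
        kb, _ = generate_random_kb(SyntheticKBParams(concept_count=90, seed=seed))
        path = tmp_path / "kb.ttl"
        save_kb(kb, path)
        kb2 = load_kb(path)
        assert compute_closure(kb).ancestors == compute_closure(kb2).ancestors

    def test_round_trip_preserves_annotations(self, tmp_path, mini_kb):
        path = tmp_path / "kb.ttl"
        save_kb(mini_kb, path)
        kb2 = load_kb(path)
        rof = kb2.concepts[RING_OF_FIRE]
        assert rof.pmids == ["18936028"]
        assert rof.pref_label("fr") == "signe de l'anneau de feu"
        uterus = kb2.concepts[concept_id("uterus")]
        assert uterus.fma_id == "17558"

    def test_unsupported_construct_warns_and_skips(self, tmp_path, mini_kb):
        path = tmp_path / "kb.ttl"
        save_kb(mini_kb, path)
        text = path.read_text(encoding="utf-8")
        text += '\nepo:OPPIO_0000189 rdfs:seeAlso "something" .\n'
        path.write_text(text, encoding="utf-8")
        with pytest.warns(TurtleSubsetWarning):
            kb2 = load_kb(path)
        assert kb_equal_modulo_categories(mini_kb, kb2)


def kb_equal_modulo_categories(a, b):
    """Equality up to category fields and disjoint-set pair expansion
    (Turtle serializes n-ary disjointness as pairwise axioms)."""

    def core(kb):
        from itertools import combinations

        from epokb.kb_core import Disjoint

        pairs = set()
        rest = []
        for ax in kb.axioms:
            if isinstance(ax, Disjoint):
                pairs.update(map(frozenset, combinations(sorted(ax.members), 2)))
            else:
                rest.append(repr(ax))
        return set(kb.concepts), sorted(rest), pairs

    return core(a) == core(b)


class TestValidate:
    def test_mini_epo_is_clean(self, mini_kb):
        assert validate_kb(mini_kb) == []

    def test_validate_is_idempotent_and_side_effect_free(self, mini_kb):
        before = sorted(map(repr, mini_kb.axioms))
        assert validate_kb(mini_kb) == validate_kb(mini_kb)
        assert sorted(map(repr, mini_kb.axioms)) == before

    def test_planted_cycle_is_reported(self, mini_kb):
        kb = mini_kb.copy()
        a, b = concept_id("ampulla"), concept_id("uterine tube")
        kb.axioms.append(SubclassOf(b, a))  # b is already an ancestor of a
        issues = validate_kb(kb)
        assert any("cycle" in i for i in issues)

    def test_sign_without_english_definition_flagged(self, mini_kb):
        kb = mini_kb.copy()
        kb.concepts[RING_OF_FIRE].definitions = [LangText("définition", "fr")]
        issues = validate_kb(kb)
        assert any("English definition" in i and RING_OF_FIRE in i for i in issues)

    def test_duplicate_pref_label_language_flagged(self, mini_kb):
        kb = mini_kb.copy()
        kb.concepts[RING_OF_FIRE].pref_labels.append(LangText("second label", "en"))
        issues = validate_kb(kb)
        assert any("preferred labels" in i for i in issues)


class TestSearch:
    def test_prefix_query_finds_ring_of_fire(self, mini_kb):
        result = search_terms(mini_kb, "ring of f", lang="en", limit=5)
        assert result[0] == RING_OF_FIRE

    def test_empty_query_returns_nothing(self, mini_kb):
        assert search_terms(mini_kb, "", lang="en", limit=5) == []

    def test_alt_label_match(self, mini_kb):
        assert RING_OF_FIRE in search_terms(mini_kb, "vascular ring", lang="en", limit=5)

    def test_exact_pref_match_ranks_first(self, mini_kb):
        result = search_terms(mini_kb, "tubal ring sign", lang="en", limit=5)
        assert result[0] == concept_id("tubal ring sign")

    def test_unknown_language_raises(self, mini_kb):
        with pytest.raises(KBError, match="configured languages"):
            search_terms(mini_kb, "ring", lang="de")

    def test_french_search_only_returns_french_labelled(self, mini_kb):
        result = search_terms(mini_kb, "anneau", lang="fr", limit=10)
        assert result == [RING_OF_FIRE]

    @given(st.text(max_size=25), st.integers(min_value=1, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_results_always_have_label_in_language(self, query, limit):
        kb = build_mini_epo()
        for cid in search_terms(kb, query, lang="fr", limit=limit):
            assert kb.concepts[cid].labels("fr")

    @given(st.sampled_from(["ring", "sac", "tubal", "mass", "sign", "view"]))
    @settings(max_examples=20, deadline=None)
    def test_search_is_stable_and_bounded(self, query):
        kb = build_mini_epo()
        r1 = search_terms(kb, query, lang="en", limit=7)
        r2 = search_terms(kb, query, lang="en", limit=7)
        assert r1 == r2
        assert len(r1) <= 7


def test_concept_ids_unique_and_stable():
    kb1, kb2 = build_mini_epo(), build_mini_epo()
    assert sorted(kb1.concepts) == sorted(kb2.concepts)
    assert len(set(kb1.concepts)) == len(kb1.concepts)


def test_langtext_requires_text():
    with pytest.raises(ValueError):
        LangText("", "en")


def test_duplicate_concept_rejected():
    kb = KnowledgeBase()
    kb.add_concept(Concept(id="epo:X"))
    with pytest.raises(KBError, match="duplicate"):
        kb.add_concept(Concept(id="epo:X"))
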
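"""Suggestion queries and competency questions."""

import random

import pytest

from epokb.fixtures import (
    SyntheticKBParams,
    concept_id,
    generate_random_kb,
    mini_epo_manifest,
    structures_in_view_oracle,
    suggest_types_oracle,
)
from epokb.kb_core import KBError
from epokb.reasoner import compute_closure, materialize_relations
from epokb.suggestion import (
    implantation_sites,
    reference_images,
    sign_profile,
    structures_in_view,
    suggest_signs_for_types,
    suggest_types_for_signs,
)

RING_OF_FIRE = concept_id("ring of fire sign")


class TestSuggestTypes:
    def test_ring_of_fire_suggests_tubal_pregnancy(self, mini_kb, mini_relations, mini_closure):
        result = suggest_types_for_signs(
            mini_kb, mini_relations, [RING_OF_FIRE], closure=mini_closure
        )
        assert [t.concept for t in result] == [concept_id("tubal pregnancy")]
        assert result[0].label.text == "tubal pregnancy"
        assert result[0].definition is not None

    def test_empty_selection(self, mini_kb, mini_relations, mini_closure):
        assert suggest_types_for_signs(mini_kb, mini_relations, [], closure=mini_closure) == []

    def test_non_sign_selection_rejected(self, mini_kb, mini_relations, mini_closure):
        with pytest.raises(KBError, match="not a sign"):
            suggest_types_for_signs(
                mini_kb, mini_relations, [concept_id("uterus")], closure=mini_closure
            )

    def test_matches_brute_force_on_random_kbs(self):
        rng = random.Random(3)
        for trial in range(25):
            kb, truth = generate_random_kb(
                SyntheticKBParams(concept_count=60, seed=300 + trial)
            )
            closure = compute_closure(kb)
            relations = materialize_relations(kb, closure)
            signs = sorted(
                c for c in kb.concepts
                if kb.sign_root in closure.of(c) and c != kb.sign_root
            )
            selection = rng.sample(signs, min(len(signs), rng.randint(1, 5)))
            got = {
                t.concept
                for t in suggest_types_for_signs(kb, relations, selection, closure=closure)
            }
            assert got == suggest_types_oracle(kb, set(selection)), trial

    def test_monotone_in_selection(self, mini_kb, mini_relations, mini_closure):
        one = {
            t.concept for t in suggest_types_for_signs(
                mini_kb, mini_relations, [RING_OF_FIRE], closure=mini_closure)
        }
        two = {
            t.concept for t in suggest_types_for_signs(
                mini_kb, mini_relations,
                [RING_OF_FIRE, concept_id("interstitial line sign")],
                closure=mini_closure)
        }
        assert one <= two

    def test_ordering_by_label(self, mini_kb, mini_relations, mini_closure):
        selection = [RING_OF_FIRE, concept_id("interstitial line sign"),
                     concept_id("caesarean section scar pregnancy peritrophoblastic blood flow")]
        result = suggest_types_for_signs(mini_kb, mini_relations, selection, closure=mini_closure)
        labels = [t.label.text.lower() for t in result]
        assert labels == sorted(labels)


class TestSuggestSigns:
    def test_tubal_pregnancy_signs(self, mini_kb, mini_relations, mini_closure):
        got = suggest_signs_for_types(
            mini_kb, mini_relations, [concept_id("tubal pregnancy")], closure=mini_closure
        )
        assert RING_OF_FIRE in got
        assert concept_id("tubal ring sign") in got

    def test_cervical_pregnancy_matches_manifest(self, mini_kb, mini_relations, mini_closure):
        got = suggest_signs_for_types(
            mini_kb, mini_relations, [concept_id("cervical pregnancy")], closure=mini_closure
        )
        assert tuple(got) == mini_epo_manifest().cervical_pregnancy_signs

    def test_empty_selection(self, mini_kb, mini_relations, mini_closure):
        assert suggest_signs_for_types(mini_kb, mini_relations, [], closure=mini_closure) == []

    def test_exclusion_list(self, mini_kb, mini_relations, mini_closure):
        got = suggest_signs_for_types(
            mini_kb, mini_relations, [concept_id("tubal pregnancy")],
            exclude=[RING_OF_FIRE], closure=mini_closure,
        )
        assert RING_OF_FIRE not in got


class TestSignProfile:
    def test_ring_of_fire_full_profile(self, mini_kb, mini_relations, mini_closure):
        prof = sign_profile(mini_kb, mini_relations, RING_OF_FIRE, closure=mini_closure)
        assert prof.suggests == (concept_id("tubal pregnancy"),)
        assert set(prof.locations) == {
            concept_id("ampulla"), concept_id("tubal isthmus"), concept_id("fimbrial portion")
        }
        assert prof.routes == (concept_id("vaginal route"),)
        assert prof.modes == (concept_id("color Doppler mode (2D)"),)
        assert prof.views == (concept_id("adnexal area view"),)

    def test_sign_without_relations_is_empty(self, mini_kb, mini_relations, mini_closure):
        prof = sign_profile(
            mini_kb, mini_relations, concept_id("intact endometrial midline echo"),
            closure=mini_closure,
        )
        assert prof.suggests == prof.locations == prof.routes == prof.modes == prof.views == ()

    def test_child_inherits_full_profile(self, mini_kb):
        from epokb.kb_core import Concept, LangText, SubclassOf

        kb = mini_kb.copy()
        child = Concept(
            id="epo:OPPIO_planted", pref_labels=[LangText("planted child sign", "en")],
            definitions=[LangText("A planted specialisation.", "en")], category="sign",
        )
        kb.concepts[child.id] = child
        kb.axioms.append(SubclassOf(child.id, RING_OF_FIRE))
        closure = compute_closure(kb)
        relations = materialize_relations(kb, closure)
        parent_prof = sign_profile(kb, relations, RING_OF_FIRE, closure=closure)
        child_prof = sign_profile(kb, relations, child.id, closure=closure)
        assert child_prof.suggests == parent_prof.suggests
        assert child_prof.locations == parent_prof.locations
        assert child_prof.modes == parent_prof.modes

    def test_unknown_concept_rejected(self, mini_kb, mini_relations, mini_closure):
        with pytest.raises(KBError):
            sign_profile(mini_kb, mini_relations, "epo:nothing", closure=mini_closure)


class TestReferenceImages:
    def test_ring_of_fire_has_pmid(self, mini_kb):
        records = reference_images(mini_kb, RING_OF_FIRE)
        assert any(r.pmid == "18936028" for r in records)

    def test_unannotated_sign_empty(self, mini_kb):
        assert reference_images(mini_kb, concept_id("tubal ring without central identifying feature")) == []

    def test_totals_match_manifest(self, mini_kb):
        manifest = mini_epo_manifest()
        pmids = sum(len(c.pmids) for c in mini_kb.concepts.values())
        images = sum(len(c.image_paths) for c in mini_kb.concepts.values())
        assert pmids == manifest.pmid_annotation_count
        assert images == manifest.image_annotation_count


class TestCompetencyQuestions:
    def test_implantation_sites_cover_the_four_types(self, mini_kb):
        sites = set(implantation_sites(mini_kb))
        assert sites >= {
            concept_id("tubal pregnancy"),
            concept_id("cervical pregnancy"),
            concept_id("interstitial pregnancy"),
            concept_id("cesarean section scar pregnancy"),
        }

    def test_no_disorders_no_sites(self):
        from epokb.kb_core import Concept, KnowledgeBase, LangText

        kb = KnowledgeBase()
        kb.add_concept(Concept(id="x", pref_labels=[LangText("x", "en")]))
        kb.sign_root = kb.disorder_root = kb.anatomy_root = "x"
        assert implantation_sites(kb) == []

    def test_synthetic_sites_equal_planted_set(self):
        kb, truth = generate_random_kb(SyntheticKBParams(concept_count=50, seed=42))
        assert set(implantation_sites(kb)) == set(truth.top_level_disorders)

    def test_structures_in_adnexal_view(self, mini_kb, mini_relations, mini_closure):
        got = set(structures_in_view(
            mini_kb, mini_relations, concept_id("adnexal area view"), closure=mini_closure
        ))
        assert got >= {
            concept_id("ampulla"), concept_id("tubal isthmus"), concept_id("fimbrial portion")
        }

    def test_unused_view_is_empty(self, mini_kb, mini_relations, mini_closure):
        assert structures_in_view(
            mini_kb, mini_relations, concept_id("longitudinal view of the uterus"),
            closure=mini_closure,
        ) == []

    def test_non_view_concept_rejected(self, mini_kb, mini_relations, mini_closure):
        with pytest.raises(KBError, match="view"):
            structures_in_view(mini_kb, mini_relations, concept_id("uterus"),
                               closure=mini_closure)

    def test_matches_brute_force_join_on_random_kbs(self):
        for trial in range(15):
            kb, _ = generate_random_kb(SyntheticKBParams(concept_count=60, seed=500 + trial))
            closure = compute_closure(kb)
            relations = materialize_relations(kb, closure)
            views = sorted(c for c in kb.concepts if "syn:VIEW" in closure.of(c))
            for view in views[:5]:
                got = set(structures_in_view(kb, relations, view, closure=closure))
                assert got == structures_in_view_oracle(kb, view), (trial, view)


def test_outputs_duplicate_free_and_stable(mini_kb, mini_relations, mini_closure):
    for _ in range(2):
        sites = implantation_sites(mini_kb)
        assert len(sites) == len(set(sites))
        signs = suggest_signs_for_types(
            mini_kb, mini_relations, [concept_id("tubal pregnancy")], closure=mini_closure
        )
        assert len(signs) == len(set(signs))
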
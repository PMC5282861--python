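"""Seeded synthetic generators: random knowledge bases with planted ground
truth, and random annotation sessions with a known gold standard.

Both generators are pure functions of their parameter objects; the same
seed always reproduces the same artifact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from ..annotation import Annotation, AnnotationSession, ImageRecord, ObserverID
from ..kb_core.model import (
    Concept,
    derive_categories,
    EquivalentToDefinition,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
)
from .oracle import infer_oracle, materialize_oracle


@dataclass(frozen=True)
class SyntheticKBParams:
    concept_count: int = 60
    max_parents: int = 2
    defined_class_count: int = 3
    restriction_density: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.concept_count < 10:
            raise ValueError("concept_count must be >= 10 (room for the six roots)")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.max_parents > self.concept_count:
            raise ValueError("max_parents exceeds the number of available ancestors")
        if not 0.0 <= self.restriction_density <= 1.0:
            raise ValueError("restriction_density must be in [0, 1]")
        if self.defined_class_count < 0:
            raise ValueError("defined_class_count must be >= 0")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted expectations, computed by the brute-force oracle route."""

    ancestors: dict[str, frozenset[str]]
    defined_edges: frozenset[tuple[str, str]]
    relations: frozenset[tuple[str, str, str]]
    top_level_disorders: frozenset[str]


_ROOTS = (
    ("syn:SIGN", "synthetic sign root"),
    ("syn:DIS", "synthetic disorder root"),
    ("syn:ANAT", "synthetic anatomy root"),
    ("syn:ROUTE", "synthetic examination route"),
    ("syn:MODE", "synthetic examination mode"),
    ("syn:VIEW", "synthetic echographic view"),
)


def generate_random_kb(
    params: SyntheticKBParams,
) -> tuple[KnowledgeBase, SyntheticGroundTruth]:
    params.validate()
    rng = random.Random(params.seed)

    kb = KnowledgeBase()
    for cid, label in _ROOTS:
        kb.add_concept(Concept(id=cid, pref_labels=[LangText(label, "en")],
                               definitions=[LangText(f"{label}.", "en")]))
    kb.sign_root = "syn:SIGN"
    kb.disorder_root = "syn:DIS"
    kb.anatomy_root = "syn:ANAT"
    kb.technical_roots = ["syn:ROUTE", "syn:MODE", "syn:VIEW"]

    budget = params.concept_count - len(_ROOTS)
    # category allocation: signs get the largest share
    n_sign = max(1, round(budget * 0.4))
    n_dis = max(1, round(budget * 0.2))
    n_anat = max(1, round(budget * 0.2))
    n_tech = max(3, budget - n_sign - n_dis - n_anat)

    by_cat: dict[str, list[str]] = {}

    def grow(category: str, root: str, count: int, roots: Optional[list[str]] = None) -> list[str]:
        members: list[str] = []
        pool = roots or [root]
        for i in range(count):
            cid = f"syn:C{len(kb.concepts)}"
            label = f"{category} {i}"
            kb.add_concept(Concept(
                id=cid,
                pref_labels=[LangText(label, "en")],
                definitions=[LangText(f"Synthetic concept {label}.", "en")],
            ))
            candidates = pool + members
            k = min(rng.randint(1, params.max_parents), len(candidates))
            for parent in rng.sample(candidates, k):
                kb.axioms.append(SubclassOf(cid, parent))
            members.append(cid)
        by_cat[category] = members
        return members

    signs = grow("sign", "syn:SIGN", n_sign)
    disorders = grow("disorder", "syn:DIS", n_dis)
    anatomy = grow("anatomy", "syn:ANAT", n_anat)
    technical = grow("technical", "", n_tech, roots=["syn:ROUTE", "syn:MODE", "syn:VIEW"])

    object_pools = {
        "suggests": disorders,
        "hasLocation": anatomy,
        "requiresRoute": technical,
        "requiresMode": technical,
        "requiresView": technical,
    }

    # plant restrictions on signs
    for s in signs:
        for prop, pool in object_pools.items():
            if pool and rng.random() < params.restriction_density / len(object_pools):
                kb.axioms.append(
                    SubclassOfRestriction(s, Restriction(prop, rng.choice(pool)))
                )

    # plant defined sign categories; identical definitions would make two
    # defined classes mutually equivalent (a subsumption cycle), so each
    # (property, filler) pair is used at most once
    used: set[tuple[str, str]] = set()
    for i in range(params.defined_class_count):
        prop = rng.choice(["suggests", "hasLocation", "requiresMode", "requires"])
        pool = object_pools.get(prop) or technical
        if not pool:
            continue
        filler = rng.choice(pool)
        if (prop, filler) in used:
            continue
        used.add((prop, filler))
        cid = f"syn:D{i}"
        kb.add_concept(Concept(
            id=cid,
            pref_labels=[LangText(f"defined sign category {i}", "en")],
            definitions=[LangText(f"Synthetic defined class {i}.", "en")],
        ))
        kb.axioms.append(EquivalentToDefinition(
            cid, "syn:SIGN", (Restriction(prop, filler),)
        ))

    derive_categories(kb)
    ancestors, defined_edges = infer_oracle(kb)
    relations = materialize_oracle(kb, ancestors)
    parents = kb.asserted_parents()
    for c, d in defined_edges:
        parents.setdefault(c, set()).add(d)
    top = frozenset(c for c, ps in parents.items() if kb.disorder_root in ps)
    truth = SyntheticGroundTruth(
        ancestors={c: frozenset(a) for c, a in ancestors.items()},
        defined_edges=frozenset(defined_edges),
        relations=frozenset(relations),
        top_level_disorders=top,
    )
    return kb, truth


@dataclass(frozen=True)
class SyntheticSessionParams:
    image_count: int = 30
    observer_count: int = 6
    sensitivity: float = 0.9
    false_positive_rate: float = 0.05
    prevalence: float = 0.3
    seed: int = 0
    cohort: str = "common"

    def validate(self) -> None:
        if self.observer_count < 2:
            raise ValueError("observer_count must be >= 2")
        if self.image_count < 1:
            raise ValueError("image_count must be >= 1")
        for name in ("sensitivity", "false_positive_rate", "prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def generate_session(
    kb: KnowledgeBase,
    params: SyntheticSessionParams,
    signs: Optional[list[str]] = None,
) -> AnnotationSession:
    """Random session: gold sign sets drawn per prevalence; each observer
    independently marks gold signs with probability ``sensitivity`` and
    non-gold signs with ``false_positive_rate``."""
    params.validate()
    if signs is None:
        from ..reasoner import compute_closure

        closure = compute_closure(kb)
        signs = sorted(
            c for c in kb.concepts
            if kb.sign_root in closure.of(c) and c != kb.sign_root
        )
    if not signs:
        raise ValueError("knowledge base has no sign concepts")

    rng = random.Random(params.seed)
    session = AnnotationSession(kb=kb)
    session.observers = [
        ObserverID(f"obs{i + 1}") for i in range(params.observer_count)
    ]
    gold: dict[str, frozenset[str]] = {}
    for i in range(params.image_count):
        image_id = f"img{i + 1:04d}"
        session.images.append(
            ImageRecord(image_id=image_id, case_id=f"case{i // 6 + 1}",
                        cohort=params.cohort)
        )
        present = frozenset(s for s in signs if rng.random() < params.prevalence)
        gold[image_id] = present
        for obs in session.observers:
            for s in signs:
                p = params.sensitivity if s in present else params.false_positive_rate
                if rng.random() < p:
                    session.annotations.add(Annotation(image_id, obs.value, s))
    session.gold = gold
    return session


def forced_panel_session(
    kb: KnowledgeBase, sign: str, k: int, x: int
) -> AnnotationSession:
    """One image on which exactly ``k`` of ``x`` observers mark ``sign``."""
    session = AnnotationSession(kb=kb)
    session.observers = [ObserverID(f"obs{i + 1}") for i in range(x)]
    session.images = [ImageRecord(image_id="img0001", case_id="case1")]
    for obs in session.observers[:k]:
        session.annotations.add(Annotation("img0001", obs.value, sign))
    session.gold = {"img0001": frozenset({sign})}
    return session
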
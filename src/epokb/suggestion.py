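"""Suggestion queries over the materialized knowledge base.

Native equivalents of the application's SPARQL rule set: suggest disorder
types for a set of selected signs, suggest further signs for selected
types, profile a sign's relations, list reference images, and answer the
competency queries (implantation sites, structures visible in a view).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .kb_core.model import KBError, KnowledgeBase, LangText
from .reasoner import (
    InferredRelation,
    SubsumptionClosure,
    compute_closure,
    inferred_parent_map,
    materialize_relations,
)

PROFILE_PROPERTIES = ("suggests", "hasLocation", "requiresRoute", "requiresMode", "requiresView")


@dataclass(frozen=True)
class TypeSuggestion:
    concept: str
    label: LangText
    definition: Optional[LangText] = None


@dataclass(frozen=True)
class SignProfile:
    sign: str
    suggests: tuple[str, ...]
    locations: tuple[str, ...]
    routes: tuple[str, ...]
    modes: tuple[str, ...]
    views: tuple[str, ...]


@dataclass(frozen=True)
class ReferenceImage:
    sign: str
    pmid: Optional[str]
    image_path: Optional[str]


def _label(kb: KnowledgeBase, cid: str, lang: str) -> LangText:
    """Preferred label with English fallback (flagged by the lang tag)."""
    c = kb.concept(cid)
    text = c.pref_label(lang)
    if text is not None:
        return LangText(text, lang)
    fallback = c.pref_label("en")
    if fallback is not None:
        return LangText(fallback, "en")
    return LangText(cid, "en")


def _definition(kb: KnowledgeBase, cid: str, lang: str) -> Optional[LangText]:
    c = kb.concept(cid)
    text = c.definition(lang) or c.definition("en")
    return LangText(text, lang if c.definition(lang) else "en") if text else None


def _label_key(kb: KnowledgeBase, cid: str, lang: str) -> tuple[str, str]:
    return (_label(kb, cid, lang).text.lower(), cid)


def top_level_disorders(kb: KnowledgeBase) -> set[str]:
    """Named classes one subsumption step under the disorder root
    (asserted or defined-class edges)."""
    parents = inferred_parent_map(kb)
    return {c for c, ps in parents.items() if kb.disorder_root in ps}


def _require_category(
    kb: KnowledgeBase, closure: SubsumptionClosure, cid: str, root: str, what: str
) -> None:
    if cid not in closure.ancestors:
        raise KBError(f"unknown concept: {cid}")
    if root not in closure.of(cid):
        raise KBError(f"{cid} is not a {what} (not under {root})")


def suggest_types_for_signs(
    kb: KnowledgeBase,
    relations: Sequence[InferredRelation],
    selected_signs: Sequence[str],
    lang: str = "en",
    closure: Optional[SubsumptionClosure] = None,
) -> list[TypeSuggestion]:
    """Disorder types having at least one of the selected signs.

    Reported at the granularity of direct children of the disorder root,
    DISTINCT, ordered by label (case-insensitive, concept-id tiebreak).
    """
    if closure is None:
        closure = compute_closure(kb)
    for s in selected_signs:
        _require_category(kb, closure, s, kb.sign_root, "sign")
    selected = set(selected_signs)
    top = top_level_disorders(kb)
    hits = {
        rel.object
        for rel in relations
        if rel.subject in selected and rel.property == "suggests" and rel.object in top
    }
    out = sorted(hits, key=lambda d: _label_key(kb, d, lang))
    return [
        TypeSuggestion(d, _label(kb, d, lang), _definition(kb, d, lang)) for d in out
    ]


def suggest_signs_for_types(
    kb: KnowledgeBase,
    relations: Sequence[InferredRelation],
    selected_types: Sequence[str],
    lang: str = "en",
    exclude: Sequence[str] = (),
    closure: Optional[SubsumptionClosure] = None,
) -> list[str]:
    """Signs with an inherited ``suggests`` to any selected type or its
    descendants, label-ordered, minus an optional exclusion list."""
    if closure is None:
        closure = compute_closure(kb)
    for t in selected_types:
        _require_category(kb, closure, t, kb.disorder_root, "disorder")
    selected = set(selected_types)
    excluded = set(exclude)
    hits = {
        rel.subject
        for rel in relations
        if rel.property == "suggests"
        and (rel.object in selected or (closure.of(rel.object) & selected))
        and rel.subject not in excluded
    }
    return sorted(hits, key=lambda s: _label_key(kb, s, lang))


def sign_profile(
    kb: KnowledgeBase,
    relations: Sequence[InferredRelation],
    sign: str,
    closure: Optional[SubsumptionClosure] = None,
) -> SignProfile:
    """Partition a sign's asserted-or-inherited relations by property.

    Filler-generalized entries are excluded so the profile reports the
    fillers at the level they were asserted.
    """
    if closure is None:
        closure = compute_closure(kb)
    _require_category(kb, closure, sign, kb.sign_root, "sign")
    buckets: dict[str, set[str]] = {p: set() for p in PROFILE_PROPERTIES}
    for rel in relations:
        if rel.subject != sign or rel.property not in buckets:
            continue
        if rel.provenance.startswith("filler_generalized"):
            continue
        buckets[rel.property].add(rel.object)
    return SignProfile(
        sign=sign,
        suggests=tuple(sorted(buckets["suggests"])),
        locations=tuple(sorted(buckets["hasLocation"])),
        routes=tuple(sorted(buckets["requiresRoute"])),
        modes=tuple(sorted(buckets["requiresMode"])),
        views=tuple(sorted(buckets["requiresView"])),
    )


def reference_images(kb: KnowledgeBase, sign: str) -> list[ReferenceImage]:
    """The sign's own PMID / image-path annotations, paired positionally."""
    c = kb.concept(sign)
    pmids = sorted(c.pmids)
    paths = sorted(c.image_paths)
    n = max(len(pmids), len(paths))
    return [
        ReferenceImage(
            sign,
            pmids[i] if i < len(pmids) else None,
            paths[i] if i < len(paths) else None,
        )
        for i in range(n)
    ]


def implantation_sites(kb: KnowledgeBase, lang: str = "en") -> list[str]:
    """Direct children of the disorder root, label-ordered."""
    return sorted(top_level_disorders(kb), key=lambda d: _label_key(kb, d, lang))


def structures_in_view(
    kb: KnowledgeBase,
    relations: Sequence[InferredRelation],
    view: str,
    closure: Optional[SubsumptionClosure] = None,
) -> list[str]:
    """Anatomical structures located by signs acquired in ``view``.

    A sign qualifies when its inherited ``requiresView`` includes the view
    or one of its descendants; the result is the union of those signs'
    asserted-level ``hasLocation`` fillers.
    """
    if closure is None:
        closure = compute_closure(kb)
    view_roots = [r for r in kb.technical_roots if _is_view_root(kb, r)]
    if view not in closure.ancestors or not any(
        r in closure.of(view) for r in view_roots
    ):
        raise KBError(f"{view} is not under an echographic-view root")
    signs = {
        rel.subject
        for rel in relations
        if rel.property == "requiresView" and view in closure.of(rel.object)
    }
    structures: set[str] = set()
    for rel in relations:
        if (
            rel.subject in signs
            and rel.property == "hasLocation"
            and not rel.provenance.startswith("filler_generalized")
        ):
            structures.add(rel.object)
    return sorted(structures)


def _is_view_root(kb: KnowledgeBase, root: str) -> bool:
    c = kb.concepts.get(root)
    label = (c.pref_label("en") or "") if c else ""
    return "view" in label.lower() or root.lower().endswith("view")


def infer_all(kb: KnowledgeBase) -> tuple[SubsumptionClosure, list[InferredRelation]]:
    """Convenience: closure plus materialized relations in one call."""
    closure = compute_closure(kb)
    return closure, materialize_relations(kb, closure)
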
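"""Structural validation of a knowledge base.

Issues are returned as data; :func:`validate_kb` never raises on bad
content, only on programming errors.  An empty issue list means all model
invariants hold: no dangling references, acyclic subsumption, every concept
reachable from a declared root, category fields consistent with ancestry,
and every sign carrying the minimal annotation set (one English preferred
label and one English definition).
"""

from __future__ import annotations

from collections import Counter

from .model import (
    CONFIGURED_LANGUAGES,
    Disjoint,
    EquivalentToDefinition,
    KnowledgeBase,
    SubclassOf,
    SubclassOfRestriction,
)


def _asserted_ancestors(kb: KnowledgeBase) -> tuple[dict[str, set[str]], list[str]]:
    """Reflexive-transitive ancestors over asserted edges; cycles reported."""
    parents = kb.asserted_parents()
    anc: dict[str, set[str]] = {}
    issues: list[str] = []
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in kb.concepts}

    def visit(n: str, stack: list[str]) -> set[str]:
        if color.get(n) == BLACK:
            return anc[n]
        if color.get(n) == GREY:
            cyc = sorted(set(stack[stack.index(n):] + [n]))
            issues.append("subsumption cycle involving {%s}" % ", ".join(cyc))
            return {n}
        if n not in color:  # dangling parent; reported elsewhere
            return {n}
        color[n] = GREY
        stack.append(n)
        result = {n}
        for p in sorted(parents.get(n, ())):
            result |= visit(p, stack)
        stack.pop()
        color[n] = BLACK
        anc[n] = result
        return result

    for n in sorted(kb.concepts):
        visit(n, [])
    return anc, issues


def validate_kb(kb: KnowledgeBase) -> list[str]:
    issues: list[str] = []

    # roots must exist
    root_names = {
        "sign_root": kb.sign_root,
        "disorder_root": kb.disorder_root,
        "anatomy_root": kb.anatomy_root,
    }
    for name, root in root_names.items():
        if not root:
            issues.append(f"{name} is not declared")
        elif root not in kb.concepts:
            issues.append(f"{name} {root!r} is not a concept in the knowledge base")
    for root in kb.technical_roots:
        if root not in kb.concepts:
            issues.append(f"technical root {root!r} is not a concept in the knowledge base")

    # concept-level invariants
    for cid in sorted(kb.concepts):
        c = kb.concepts[cid]
        if not cid:
            issues.append("concept with empty id")
        if c.id != cid:
            issues.append(f"concept keyed {cid!r} carries id {c.id!r}")
        per_lang = Counter(lt.lang for lt in c.pref_labels)
        for lang, n in per_lang.items():
            if n > 1:
                issues.append(f"{cid}: {n} preferred labels for language {lang!r}")
        for lt in c.pref_labels + c.alt_labels + c.definitions:
            if lt.lang not in CONFIGURED_LANGUAGES:
                issues.append(f"{cid}: unconfigured language {lt.lang!r}")

    # referential integrity of axioms
    def known(ref: str) -> bool:
        return ref in kb.concepts

    for ax in kb.axioms:
        if isinstance(ax, SubclassOf):
            for ref in (ax.child, ax.parent):
                if not known(ref):
                    issues.append(f"subclass axiom references unknown concept {ref!r}")
        elif isinstance(ax, SubclassOfRestriction):
            if not known(ax.child):
                issues.append(f"restriction axiom references unknown concept {ax.child!r}")
            if not known(ax.restriction.filler):
                issues.append(
                    f"restriction filler {ax.restriction.filler!r} is not a concept"
                )
            if ax.restriction.property not in kb.properties:
                issues.append(
                    f"restriction uses unknown property {ax.restriction.property!r}"
                )
        elif isinstance(ax, EquivalentToDefinition):
            if not known(ax.cls):
                issues.append(f"definition for unknown concept {ax.cls!r}")
            if not known(ax.genus):
                issues.append(f"definition genus {ax.genus!r} is not a concept")
            if not ax.restrictions:
                issues.append(f"definition of {ax.cls!r} has no restrictions")
            for r in ax.restrictions:
                if not known(r.filler):
                    issues.append(f"definition filler {r.filler!r} is not a concept")
                if r.property not in kb.properties:
                    issues.append(f"definition uses unknown property {r.property!r}")
        elif isinstance(ax, Disjoint):
            if len(ax.members) < 2:
                issues.append("disjointness axiom with fewer than 2 members")
            for m in ax.members:
                if not known(m):
                    issues.append(f"disjointness references unknown concept {m!r}")

    # property hierarchy must be a forest
    for prop, parent in kb.properties.items():
        if parent is not None and parent not in kb.properties:
            issues.append(f"property {prop!r} has unknown parent {parent!r}")
        seen = set()
        cur = prop
        while cur is not None:
            if cur in seen:
                issues.append(f"property hierarchy cycle at {prop!r}")
                break
            seen.add(cur)
            cur = kb.properties.get(cur)

    if issues:
        # structural problems make ancestry unreliable; stop here
        return issues

    anc, cycle_issues = _asserted_ancestors(kb)
    issues.extend(cycle_issues)
    if cycle_issues:
        return issues

    roots = set(kb.roots)
    for cid in sorted(kb.concepts):
        if cid in roots:
            continue
        if not (anc[cid] & roots):
            issues.append(f"{cid} is not reachable from any declared root")

    # sign annotation minimum and category consistency
    tech = set(kb.technical_roots)
    for cid in sorted(kb.concepts):
        c = kb.concepts[cid]
        if kb.sign_root in anc[cid]:
            expected = "sign"
        elif kb.disorder_root in anc[cid]:
            expected = "disorder"
        elif kb.anatomy_root in anc[cid]:
            expected = "anatomy"
        elif anc[cid] & tech:
            expected = "technical"
        else:
            expected = "other"
        if c.category != expected:
            issues.append(
                f"{cid}: category {c.category!r} inconsistent with ancestry "
                f"({expected!r} expected)"
            )
        if expected == "sign":
            if c.pref_label("en") is None:
                issues.append(f"{cid}: sign concept lacks an English preferred label")
            if c.definition("en") is None:
                issues.append(f"{cid}: sign concept lacks an English definition")

    return issues
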
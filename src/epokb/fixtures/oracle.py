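"""Brute-force reference implementations of the reasoning operations.

These deliberately share no code with :mod:`epokb.reasoner`: the closure is
computed by boolean matrix powers (numpy), classification by naive nested
loops iterated to fixpoint, and materialization by exhaustive enumeration
over (sign, ancestor, restriction, filler-ancestor).  They exist so the
fast implementations can be checked against an independent route, and they
provide the planted ground truth for the synthetic generator.
"""

from __future__ import annotations

import numpy as np

from ..kb_core.model import KnowledgeBase, Restriction, SubclassOfRestriction


def _property_up(kb: KnowledgeBase, prop: str) -> list[str]:
    chain = []
    cur = prop
    while cur is not None and cur not in chain:
        chain.append(cur)
        cur = kb.properties.get(cur)
    return chain


def _asserted_restriction_map(kb: KnowledgeBase) -> dict[str, set[Restriction]]:
    out: dict[str, set[Restriction]] = {}
    for ax in kb.axioms:
        if isinstance(ax, SubclassOfRestriction):
            out.setdefault(ax.child, set()).add(ax.restriction)
    return out


def _reach(adj: np.ndarray) -> np.ndarray:
    """Reflexive-transitive closure by repeated boolean squaring."""
    n = adj.shape[0]
    reach = adj | np.eye(n, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            return reach
        reach = nxt


def infer_oracle(kb: KnowledgeBase):
    """(ancestor map, defined-class edge set) by exhaustive fixpoint."""
    ids = sorted(kb.concepts)
    idx = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for child, parents in kb.asserted_parents().items():
        for p in parents:
            adj[idx[child], idx[p]] = True

    direct = kb.direct_restrictions()
    definitions = list(kb.definition_axioms())
    defined_edges: set[tuple[str, str]] = set()

    while True:
        reach = _reach(adj)

        def carried(c: str) -> set[Restriction]:
            acc: set[Restriction] = set()
            for j in range(n):
                if reach[idx[c], j]:
                    acc |= direct.get(ids[j], set())
            return acc

        added = False
        for d in definitions:
            for c in ids:
                if c == d.cls or reach[idx[c], idx[d.cls]]:
                    continue
                if not reach[idx[c], idx[d.genus]]:
                    continue
                have = carried(c)
                ok = True
                for req in d.restrictions:
                    hit = False
                    for r in have:
                        if req.property in _property_up(kb, r.property) and \
                                reach[idx[r.filler], idx[req.filler]]:
                            hit = True
                            break
                    if not hit:
                        ok = False
                        break
                if ok:
                    adj[idx[c], idx[d.cls]] = True
                    defined_edges.add((c, d.cls))
                    added = True
        if not added:
            ancestors = {
                c: frozenset(ids[j] for j in range(n) if reach[idx[c], j])
                for c in ids
            }
            return ancestors, defined_edges


def materialize_oracle(kb: KnowledgeBase, ancestors=None) -> set[tuple[str, str, str]]:
    """All (sign, property, object) triples, by exhaustive enumeration."""
    if ancestors is None:
        ancestors, _ = infer_oracle(kb)
    direct = _asserted_restriction_map(kb)

    def roots_for(p: str) -> list[str]:
        if p == "suggests":
            return [kb.disorder_root]
        if p == "hasLocation":
            return [kb.anatomy_root]
        return list(kb.technical_roots)

    out: set[tuple[str, str, str]] = set()
    for s in kb.concepts:
        if kb.sign_root not in ancestors[s]:
            continue
        for s_prime in ancestors[s]:
            for r in direct.get(s_prime, set()):
                for p in _property_up(kb, r.property):
                    roots = roots_for(p)
                    for c in ancestors.get(r.filler, frozenset()):
                        if c in roots:
                            continue
                        if any(root in ancestors.get(c, frozenset()) for root in roots):
                            out.add((s, p, c))
    return out


def suggest_types_oracle(
    kb: KnowledgeBase, selected_signs: set[str], ancestors=None
) -> set[str]:
    """Direct SPARQL-style evaluation: disorders one step under the root
    reachable from a someValuesFrom filler of an inherited suggests
    restriction of a selected sign."""
    if ancestors is None:
        ancestors, _ = infer_oracle(kb)
    parents = kb.asserted_parents()
    # include defined-class direct edges
    _, defined = infer_oracle(kb)
    for c, d in defined:
        parents.setdefault(c, set()).add(d)
    top = {c for c, ps in parents.items() if kb.disorder_root in ps}
    direct = _asserted_restriction_map(kb)
    hits: set[str] = set()
    for sign in selected_signs:
        for anc in ancestors[sign]:
            for r in direct.get(anc, set()):
                if "suggests" not in _property_up(kb, r.property):
                    continue
                for disorder in top:
                    if disorder in ancestors.get(r.filler, frozenset()):
                        hits.add(disorder)
    return hits


def structures_in_view_oracle(
    kb: KnowledgeBase, view: str, ancestors=None
) -> set[str]:
    if ancestors is None:
        ancestors, _ = infer_oracle(kb)
    direct = _asserted_restriction_map(kb)
    signs = set()
    for s in kb.concepts:
        if kb.sign_root not in ancestors[s]:
            continue
        for anc in ancestors[s]:
            for r in direct.get(anc, set()):
                if "requiresView" in _property_up(kb, r.property) and \
                        view in ancestors.get(r.filler, frozenset()):
                    signs.add(s)
    out: set[str] = set()
    for s in signs:
        for anc in ancestors[s]:
            for r in direct.get(anc, set()):
                if "hasLocation" in _property_up(kb, r.property):
                    out.add(r.filler)
    return out
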
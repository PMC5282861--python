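"""Subsumption closure, defined-class classification and relation
materialization.

This is a purpose-built replacement for a tableau reasoner, restricted to
the EL-style fragment of the data model: reflexive-transitive subsumption,
defined classes (named genus plus existential restrictions), subproperty
expansion, and disjointness checking.  Classification and closure are
mutually recursive, so both are computed together by fixpoint iteration and
exposed through thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .kb_core.model import (
    EquivalentToDefinition,
    KBValidationError,
    KnowledgeBase,
    Restriction,
)

__all__ = [
    "SubsumptionClosure",
    "InferredEdge",
    "InferredRelation",
    "ConsistencyReport",
    "compute_closure",
    "classify_defined",
    "materialize_relations",
    "check_consistency",
]


@dataclass(frozen=True)
class SubsumptionClosure:
    """Reflexive-transitive ancestor sets, including defined-class edges."""

    ancestors: dict[str, frozenset[str]]

    def __contains__(self, cid: str) -> bool:
        return cid in self.ancestors

    def of(self, cid: str) -> frozenset[str]:
        return self.ancestors[cid]

    def is_subclass(self, child: str, parent: str) -> bool:
        return parent in self.ancestors.get(child, frozenset())


@dataclass(frozen=True, order=True)
class InferredEdge:
    child: str
    parent: str
    provenance: str  # "asserted" | "defined_class"


@dataclass(frozen=True, order=True)
class InferredRelation:
    subject: str
    property: str
    object: str
    provenance: str  # "asserted" | "inherited_from:<id>" | "filler_generalized:<id>"


@dataclass(frozen=True)
class ConsistencyReport:
    violations: tuple[tuple[str, str, str], ...]  # (concept, disjoint_a, disjoint_b)

    @property
    def consistent(self) -> bool:
        return not self.violations


def _transitive_closure(
    nodes: list[str], parents: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Reflexive-transitive ancestors by memoized DFS; cycles are fatal."""
    anc: dict[str, set[str]] = {}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}

    def visit(n: str, stack: list[str]) -> set[str]:
        if color[n] == BLACK:
            return anc[n]
        if color[n] == GREY:
            cycle = stack[stack.index(n):] + [n]
            raise KBValidationError(
                ["subsumption cycle: " + " -> ".join(cycle)]
            )
        color[n] = GREY
        stack.append(n)
        result = {n}
        for p in sorted(parents.get(n, ())):
            result |= visit(p, stack)
        stack.pop()
        color[n] = BLACK
        anc[n] = result
        return result

    for n in nodes:
        visit(n, [])
    return anc


def _inherited_restrictions(
    kb: KnowledgeBase, anc: dict[str, set[str]]
) -> dict[str, set[Restriction]]:
    direct = kb.direct_restrictions()
    out: dict[str, set[Restriction]] = {}
    for cid in kb.concepts:
        acc: set[Restriction] = set()
        for a in anc[cid]:
            acc |= direct.get(a, set())
        out[cid] = acc
    return out


def _satisfies(
    kb: KnowledgeBase,
    carried: set[Restriction],
    required: Restriction,
    anc: dict[str, set[str]],
) -> bool:
    """Does some carried ``p' some C'`` entail ``required``?

    Requires ``p'`` at-or-below the required property and ``C'`` subsumed by
    the required filler.
    """
    for r in carried:
        if required.property in kb.property_ancestors(r.property) and \
                required.filler in anc.get(r.filler, set()):
            return True
    return False


def _infer(kb: KnowledgeBase) -> tuple[dict[str, set[str]], list[InferredEdge]]:
    """Fixpoint: closure over asserted edges plus defined-class memberships."""
    nodes = sorted(kb.concepts)
    parents = kb.asserted_parents()
    definitions = sorted(
        kb.definition_axioms(), key=lambda d: d.cls
    )
    new_edges: list[InferredEdge] = []
    while True:
        anc = _transitive_closure(nodes, parents)
        carried = _inherited_restrictions(kb, anc)
        changed = False
        for d in definitions:
            for cid in nodes:
                if cid == d.cls or d.cls in anc[cid]:
                    continue
                if d.genus not in anc[cid]:
                    continue
                if all(_satisfies(kb, carried[cid], r, anc) for r in d.restrictions):
                    if cid in anc[d.cls]:
                        raise KBValidationError(
                            [f"classification would create a cycle between "
                             f"{cid} and {d.cls}"]
                        )
                    parents.setdefault(cid, set()).add(d.cls)
                    new_edges.append(InferredEdge(cid, d.cls, "defined_class"))
                    changed = True
        if not changed:
            return anc, sorted(new_edges)


def compute_closure(kb: KnowledgeBase) -> SubsumptionClosure:
    """Reflexive-transitive subsumption closure, defined classes included."""
    anc, _ = _infer(kb)
    return SubsumptionClosure({c: frozenset(a) for c, a in anc.items()})


def classify_defined(kb: KnowledgeBase) -> list[InferredEdge]:
    """New parent edges contributed by defined-class equivalences."""
    _, edges = _infer(kb)
    return edges


def inferred_parent_map(kb: KnowledgeBase) -> dict[str, set[str]]:
    """Direct parents: asserted edges plus defined-class memberships."""
    parents = kb.asserted_parents()
    for e in classify_defined(kb):
        parents.setdefault(e.child, set()).add(e.parent)
    return parents


def _object_root(kb: KnowledgeBase, prop: str) -> list[str]:
    """Category root(s) under which fillers of ``prop`` are reported."""
    if prop == "suggests":
        return [kb.disorder_root]
    if prop == "hasLocation":
        return [kb.anatomy_root]
    return list(kb.technical_roots)


def _prov_rank(prov: str) -> int:
    if prov == "asserted":
        return 0
    if prov.startswith("inherited_from"):
        return 1
    return 2


def materialize_relations(
    kb: KnowledgeBase, closure: Optional[SubsumptionClosure] = None
) -> list[InferredRelation]:
    """Propagate asserted restrictions through subsumption.

    Emits ``(sign, p, c)`` whenever an ancestor of the sign carries a
    restriction ``p' some c'`` with ``p' ⊑ p`` and ``c`` a named ancestor of
    ``c'`` that lies under the category root appropriate for ``p``
    (excluding the root itself).
    """
    if closure is None:
        closure = compute_closure(kb)
    anc = closure.ancestors
    direct = kb.asserted_restrictions()
    signs = sorted(c for c in kb.concepts if kb.sign_root in anc[c])

    best: dict[tuple[str, str, str], InferredRelation] = {}
    for s in signs:
        for s_prime in sorted(anc[s]):
            for r in sorted(direct.get(s_prime, ())):
                for p in sorted(kb.property_ancestors(r.property)):
                    roots = _object_root(kb, p)
                    for c in sorted(anc.get(r.filler, ())):
                        if c in roots:
                            continue
                        if not any(root in anc.get(c, ()) for root in roots):
                            continue
                        if c != r.filler or p != r.property:
                            prov = f"filler_generalized:{r.filler}"
                        elif s_prime != s:
                            prov = f"inherited_from:{s_prime}"
                        else:
                            prov = "asserted"
                        key = (s, p, c)
                        old = best.get(key)
                        if old is None or (
                            (_prov_rank(prov), prov)
                            < (_prov_rank(old.provenance), old.provenance)
                        ):
                            best[key] = InferredRelation(s, p, c, prov)
    return sorted(best.values())


def check_consistency(
    kb: KnowledgeBase, closure: Optional[SubsumptionClosure] = None
) -> ConsistencyReport:
    """Report concepts subsumed by two declared-disjoint classes."""
    if closure is None:
        closure = compute_closure(kb)
    violations: list[tuple[str, str, str]] = []
    for ax in kb.disjoint_axioms():
        members = sorted(ax.members)
        for cid in sorted(kb.concepts):
            anc = closure.of(cid)
            hit = [m for m in members if m in anc]
            for i in range(len(hit)):
                for j in range(i + 1, len(hit)):
                    violations.append((cid, hit[i], hit[j]))
    return ConsistencyReport(tuple(sorted(set(violations))))
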
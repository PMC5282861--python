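"""Data model for the sign-centric knowledge base.

A :class:`KnowledgeBase` bundles named concepts, a small fixed hierarchy of
object properties, logical axioms (subsumption, existential restrictions,
defined classes, disjointness) and the designated category roots (signs,
disorders, anatomy, technical elements).  The model deliberately covers only
an EL-style fragment: conjunction of a named genus with existential
restrictions, plus subproperty expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

CONFIGURED_LANGUAGES = ("en", "fr")

CATEGORIES = ("sign", "disorder", "anatomy", "technical", "other")

#: Fixed object-property hierarchy: property -> parent property (or None).
#: The three acquisition properties specialise ``requires``.
DEFAULT_PROPERTIES: dict[str, Optional[str]] = {
    "suggests": None,
    "hasLocation": None,
    "requires": None,
    "requiresRoute": "requires",
    "requiresMode": "requires",
    "requiresView": "requires",
}


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBFormatError(KBError):
    """Raised when a serialized knowledge base cannot be parsed."""


class KBValidationError(KBError):
    """Raised when a knowledge base violates structural invariants."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


@dataclass(frozen=True, order=True)
class LangText:
    """A language-tagged string (``"en"`` or ``"fr"``)."""

    text: str
    lang: str = "en"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("LangText.text must be non-empty")


@dataclass
class Concept:
    """A named class with SKOS-style annotations and provenance."""

    id: str
    pref_labels: list[LangText] = field(default_factory=list)
    alt_labels: list[LangText] = field(default_factory=list)
    definitions: list[LangText] = field(default_factory=list)
    hidden_label: Optional[str] = None
    fma_id: Optional[str] = None
    pmids: list[str] = field(default_factory=list)
    image_paths: list[str] = field(default_factory=list)
    category: str = "other"

    def pref_label(self, lang: str = "en") -> Optional[str]:
        for lt in self.pref_labels:
            if lt.lang == lang:
                return lt.text
        return None

    def definition(self, lang: str = "en") -> Optional[str]:
        for lt in self.definitions:
            if lt.lang == lang:
                return lt.text
        return None

    def labels(self, lang: str) -> list[str]:
        return [lt.text for lt in self.pref_labels + self.alt_labels if lt.lang == lang]


@dataclass(frozen=True, order=True)
class Restriction:
    """Existential restriction ``property some filler``."""

    property: str
    filler: str


@dataclass(frozen=True)
class SubclassOf:
    child: str
    parent: str


@dataclass(frozen=True)
class SubclassOfRestriction:
    child: str
    restriction: Restriction


@dataclass(frozen=True)
class EquivalentToDefinition:
    """Defined class: ``cls == genus AND restriction AND ...``."""

    cls: str
    genus: str
    restrictions: tuple[Restriction, ...]


@dataclass(frozen=True)
class Disjoint:
    members: frozenset[str]


Axiom = SubclassOf | SubclassOfRestriction | EquivalentToDefinition | Disjoint


@dataclass
class KnowledgeBase:
    concepts: dict[str, Concept] = field(default_factory=dict)
    properties: dict[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTIES)
    )
    axioms: list[Axiom] = field(default_factory=list)
    sign_root: str = ""
    disorder_root: str = ""
    anatomy_root: str = ""
    technical_roots: list[str] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------

    @property
    def roots(self) -> list[str]:
        return [self.sign_root, self.disorder_root, self.anatomy_root, *self.technical_roots]

    def concept(self, cid: str) -> Concept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise KBError(f"unknown concept: {cid}") from None

    def add_concept(self, concept: Concept) -> Concept:
        if concept.id in self.concepts:
            raise KBError(f"duplicate concept id: {concept.id}")
        self.concepts[concept.id] = concept
        return concept

    def subclass_axioms(self) -> Iterator[SubclassOf]:
        return (a for a in self.axioms if isinstance(a, SubclassOf))

    def restriction_axioms(self) -> Iterator[SubclassOfRestriction]:
        return (a for a in self.axioms if isinstance(a, SubclassOfRestriction))

    def definition_axioms(self) -> Iterator[EquivalentToDefinition]:
        return (a for a in self.axioms if isinstance(a, EquivalentToDefinition))

    def disjoint_axioms(self) -> Iterator[Disjoint]:
        return (a for a in self.axioms if isinstance(a, Disjoint))

    def asserted_parents(self) -> dict[str, set[str]]:
        """child -> set of named asserted parents.

        Includes ``SubclassOf`` edges and the genus edge implied by each
        defined-class equivalence (``cls == genus AND ...`` entails
        ``cls subClassOf genus``).
        """
        parents: dict[str, set[str]] = {cid: set() for cid in self.concepts}
        for ax in self.axioms:
            if isinstance(ax, SubclassOf):
                parents.setdefault(ax.child, set()).add(ax.parent)
            elif isinstance(ax, EquivalentToDefinition):
                parents.setdefault(ax.cls, set()).add(ax.genus)
        return parents

    def asserted_restrictions(self) -> dict[str, set[Restriction]]:
        """Restrictions asserted with ``subClassOf`` axioms only.

        Relation materialization propagates these; defined-class
        *definition* restrictions are definitional knowledge and contribute
        to classification, not to the sign-relation graph.
        """
        out: dict[str, set[Restriction]] = {cid: set() for cid in self.concepts}
        for ax in self.axioms:
            if isinstance(ax, SubclassOfRestriction):
                out.setdefault(ax.child, set()).add(ax.restriction)
        return out

    def direct_restrictions(self) -> dict[str, set[Restriction]]:
        """Restrictions each concept carries directly.

        Both asserted ``subClassOf`` restrictions and the necessary side of
        defined-class equivalences contribute.
        """
        out: dict[str, set[Restriction]] = {cid: set() for cid in self.concepts}
        for ax in self.axioms:
            if isinstance(ax, SubclassOfRestriction):
                out.setdefault(ax.child, set()).add(ax.restriction)
            elif isinstance(ax, EquivalentToDefinition):
                out.setdefault(ax.cls, set()).update(ax.restrictions)
        return out

    def property_ancestors(self, prop: str) -> set[str]:
        """Reflexive-transitive ancestors of ``prop`` in the property tree."""
        seen: set[str] = set()
        cur: Optional[str] = prop
        while cur is not None and cur not in seen:
            seen.add(cur)
            cur = self.properties.get(cur)
        return seen

    def copy(self) -> "KnowledgeBase":
        return KnowledgeBase(
            concepts={cid: replace(c,
                                   pref_labels=list(c.pref_labels),
                                   alt_labels=list(c.alt_labels),
                                   definitions=list(c.definitions),
                                   pmids=list(c.pmids),
                                   image_paths=list(c.image_paths))
                      for cid, c in self.concepts.items()},
            properties=dict(self.properties),
            axioms=list(self.axioms),
            sign_root=self.sign_root,
            disorder_root=self.disorder_root,
            anatomy_root=self.anatomy_root,
            technical_roots=list(self.technical_roots),
        )


def _concept_key(c: Concept) -> tuple:
    return (
        c.id,
        sorted(c.pref_labels),
        sorted(c.alt_labels),
        sorted(c.definitions),
        c.hidden_label,
        c.fma_id,
        sorted(c.pmids),
        sorted(c.image_paths),
        c.category,
    )


def kb_equal(a: KnowledgeBase, b: KnowledgeBase) -> bool:
    """Field-by-field structural equality; annotation lists and axiom
    lists are compared as multisets (order is not significant)."""
    if a.concepts.keys() != b.concepts.keys():
        return False
    for cid in a.concepts:
        if _concept_key(a.concepts[cid]) != _concept_key(b.concepts[cid]):
            return False
    return (
        a.properties == b.properties
        and sorted(map(repr, a.axioms)) == sorted(map(repr, b.axioms))
        and a.sign_root == b.sign_root
        and a.disorder_root == b.disorder_root
        and a.anatomy_root == b.anatomy_root
        and a.technical_roots == b.technical_roots
    )


def assign_categories(kb: KnowledgeBase, ancestors: dict[str, set[str]]) -> None:
    """Set each concept's category from its ancestry under the roots."""
    tech = set(kb.technical_roots)
    for cid, concept in kb.concepts.items():
        anc = ancestors.get(cid, {cid})
        if kb.sign_root in anc:
            concept.category = "sign"
        elif kb.disorder_root in anc:
            concept.category = "disorder"
        elif kb.anatomy_root in anc:
            concept.category = "anatomy"
        elif anc & tech:
            concept.category = "technical"
        else:
            concept.category = "other"


def derive_categories(kb: KnowledgeBase) -> None:
    """Assign categories from asserted ancestry (cycle-tolerant)."""
    parents = kb.asserted_parents()
    anc: dict[str, set[str]] = {}

    def up(n: str, seen: frozenset[str]) -> set[str]:
        if n in anc:
            return anc[n]
        if n in seen:
            return {n}
        result = {n}
        for p in parents.get(n, ()):
            if p in kb.concepts:
                result |= up(p, seen | {n})
        anc[n] = result
        return result

    for cid in kb.concepts:
        up(cid, frozenset())
    assign_categories(kb, anc)


def iter_concept_ids(kb: KnowledgeBase) -> Iterable[str]:
    return sorted(kb.concepts)
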
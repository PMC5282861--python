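"""Turtle import/export for a restricted OWL subset.

The dialect covers exactly what the data model can express:

* ``rdfs:subClassOf`` with a named class or an ``owl:Restriction`` node
  (``owl:onProperty`` + ``owl:someValuesFrom``),
* ``owl:equivalentClass`` with an ``owl:intersectionOf`` of one named genus
  and one or more restrictions,
* ``owl:disjointWith`` between named classes,
* SKOS ``prefLabel`` / ``altLabel`` / ``definition`` / ``hiddenLabel``,
* ``epo:PMID`` / ``epo:ImagePath`` / ``epo:FMAID`` annotation literals,
* ``rdfs:subPropertyOf`` between declared object properties,
* root designation triples on the ontology header node.

Constructs outside the subset are skipped with a :class:`TurtleSubsetWarning`.
No general-purpose RDF stack is available in the target environment, so the
reader is a small hand-rolled tokenizer/parser specialised to this subset.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Any, Optional

from .model import (
    Concept,
    DEFAULT_PROPERTIES,
    Disjoint,
    EquivalentToDefinition,
    KBFormatError,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
    derive_categories,
)

PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "epo": "http://www.semanticweb.org/ontologies/epo.owl#",
    "syn": "urn:example:synthetic#",
}

ONTOLOGY_NODE = "epo:thisKnowledgeBase"


class TurtleSubsetWarning(UserWarning):
    """Emitted when an imported construct falls outside the subset."""


# ---------------------------------------------------------------------------
# export


def _lit(text: str, lang: Optional[str] = None) -> str:
    escaped = text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
    return f'"{escaped}"' + (f"@{lang}" if lang else "")


def _restriction_node(r: Restriction) -> str:
    return (
        "[ a owl:Restriction ; owl:onProperty epo:%s ; owl:someValuesFrom %s ]"
        % (r.property, r.filler)
    )


def save_kb_turtle(kb: KnowledgeBase, path: str | Path) -> None:
    lines: list[str] = []
    for pfx in sorted(PREFIXES):
        lines.append(f"@prefix {pfx}: <{PREFIXES[pfx]}> .")
    lines.append("")

    lines.append(f"{ONTOLOGY_NODE} a owl:Ontology ;")
    lines.append(f"    epo:signRoot {kb.sign_root} ;")
    lines.append(f"    epo:disorderRoot {kb.disorder_root} ;")
    lines.append(f"    epo:anatomyRoot {kb.anatomy_root} ;")
    lines.append(
        "    epo:technicalRoot " + ", ".join(kb.technical_roots) + " ."
    )
    lines.append("")

    for prop in sorted(kb.properties):
        parent = kb.properties[prop]
        if parent is None:
            lines.append(f"epo:{prop} a owl:ObjectProperty .")
        else:
            lines.append(
                f"epo:{prop} a owl:ObjectProperty ; rdfs:subPropertyOf epo:{parent} ."
            )
    lines.append("")

    # axiom lookup per concept, deterministic ordering throughout
    sub: dict[str, list[str]] = {}
    sub_r: dict[str, list[Restriction]] = {}
    eq: dict[str, list[EquivalentToDefinition]] = {}
    disjoint_pairs: set[tuple[str, str]] = set()
    for ax in kb.axioms:
        if isinstance(ax, SubclassOf):
            sub.setdefault(ax.child, []).append(ax.parent)
        elif isinstance(ax, SubclassOfRestriction):
            sub_r.setdefault(ax.child, []).append(ax.restriction)
        elif isinstance(ax, EquivalentToDefinition):
            eq.setdefault(ax.cls, []).append(ax)
        elif isinstance(ax, Disjoint):
            members = sorted(ax.members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    disjoint_pairs.add((members[i], members[j]))

    for cid in sorted(kb.concepts):
        c = kb.concepts[cid]
        parts: list[str] = [f"{cid} a owl:Class"]
        for lt in sorted(c.pref_labels):
            parts.append(f"skos:prefLabel {_lit(lt.text, lt.lang)}")
        for lt in sorted(c.alt_labels):
            parts.append(f"skos:altLabel {_lit(lt.text, lt.lang)}")
        for lt in sorted(c.definitions):
            parts.append(f"skos:definition {_lit(lt.text, lt.lang)}")
        if c.hidden_label:
            parts.append(f"skos:hiddenLabel {_lit(c.hidden_label)}")
        if c.fma_id:
            parts.append(f"epo:FMAID {_lit(c.fma_id)}")
        for pmid in sorted(c.pmids):
            parts.append(f"epo:PMID {_lit(pmid)}")
        for ip in sorted(c.image_paths):
            parts.append(f"epo:ImagePath {_lit(ip)}")
        for parent in sorted(sub.get(cid, [])):
            parts.append(f"rdfs:subClassOf {parent}")
        for r in sorted(sub_r.get(cid, [])):
            parts.append(f"rdfs:subClassOf {_restriction_node(r)}")
        for d in sorted(eq.get(cid, []), key=lambda d: (d.genus, d.restrictions)):
            inner = " ".join([d.genus] + [_restriction_node(r) for r in d.restrictions])
            parts.append(
                f"owl:equivalentClass [ a owl:Class ; owl:intersectionOf ( {inner} ) ]"
            )
        for a, b in sorted(disjoint_pairs):
            if a == cid:
                parts.append(f"owl:disjointWith {b}")
        lines.append(" ;\n    ".join(parts) + " .")
        lines.append("")

    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# import

_TOKEN_RE = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<string>"(?:[^"\\]|\\.)*")(?:@(?P<lang>[A-Za-z][A-Za-z0-9-]*))?
    | (?P<iriref><[^>]*>)
    | (?P<punct>[.;,\[\]()])
    | (?P<atprefix>@prefix)
    | (?P<pname>[A-Za-z_][\w.-]*:[\w.-]*|a\b)
    | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, Any, int]]:
    tokens: list[tuple[str, Any, int]] = []
    pos = 0
    line = 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise KBFormatError(f"Turtle syntax error at line {line}: {text[pos:pos+30]!r}")
        kind = "string" if m.group("string") else m.lastgroup
        val = m.group()
        if kind == "string":
            raw = m.group("string")[1:-1]
            unescaped = (
                raw.replace("\\n", "\n").replace('\\"', '"').replace("\\\\", "\\")
            )
            tokens.append(("literal", (unescaped, m.group("lang")), line))
        elif kind == "iriref":
            tokens.append(("iri", val[1:-1], line))
        elif kind == "punct":
            tokens.append((val, val, line))
        elif kind == "atprefix":
            tokens.append(("@prefix", val, line))
        elif kind == "pname":
            tokens.append(("pname", val, line))
        line += val.count("\n")
        pos = m.end()
    return tokens


class _Parser:
    """Parses token stream into (subject, predicate, object) with structured
    objects: str curie, ("literal", text, lang), dict blank node, list."""

    def __init__(self, tokens: list[tuple[str, Any, int]]):
        self.tokens = tokens
        self.i = 0
        self.triples: list[tuple[Any, str, Any]] = []

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, -1)

    def _next(self):
        tok = self._peek()
        if tok[0] is None:
            raise KBFormatError("unexpected end of Turtle input")
        self.i += 1
        return tok

    def _expect(self, kind: str):
        tok = self._next()
        if tok[0] != kind:
            raise KBFormatError(
                f"line {tok[2]}: expected {kind!r}, found {tok[1]!r}"
            )
        return tok

    def parse(self) -> list[tuple[Any, str, Any]]:
        while self._peek()[0] is not None:
            if self._peek()[0] == "@prefix":
                self._next()
                self._expect("pname")
                self._expect("iri")
                self._expect(".")
                continue
            subject = self._node()
            self._predicate_object_list(subject)
            self._expect(".")
        return self.triples

    def _node(self) -> Any:
        kind, val, ln = self._next()
        if kind == "pname":
            return "rdf:type" if val == "a" else val
        if kind == "iri":
            return f"<{val}>"
        if kind == "[":
            blank: dict[str, list[Any]] = {}
            if self._peek()[0] != "]":
                self._blank_predicate_object_list(blank)
            self._expect("]")
            return blank
        if kind == "(":
            items = []
            while self._peek()[0] != ")":
                items.append(self._node())
            self._expect(")")
            return items
        if kind == "literal":
            return ("literal",) + val
        raise KBFormatError(f"line {ln}: unexpected token {val!r}")

    def _predicate_object_list(self, subject: Any) -> None:
        while True:
            pred = self._node()
            if not isinstance(pred, str):
                raise KBFormatError("predicate must be an IRI")
            while True:
                obj = self._node()
                self.triples.append((subject, pred, obj))
                if self._peek()[0] == ",":
                    self._next()
                    continue
                break
            if self._peek()[0] == ";":
                self._next()
                if self._peek()[0] in (".", "]"):  # trailing semicolon
                    return
                continue
            return

    def _blank_predicate_object_list(self, blank: dict[str, list[Any]]) -> None:
        while True:
            pred = self._node()
            while True:
                obj = self._node()
                blank.setdefault(pred, []).append(obj)
                if self._peek()[0] == ",":
                    self._next()
                    continue
                break
            if self._peek()[0] == ";":
                self._next()
                if self._peek()[0] == "]":
                    return
                continue
            return


def _warn(msg: str) -> None:
    warnings.warn(msg, TurtleSubsetWarning, stacklevel=3)


def _as_restriction(node: Any) -> Optional[Restriction]:
    if not isinstance(node, dict):
        return None
    types = node.get("rdf:type", [])
    if "owl:Restriction" not in types:
        return None
    props = node.get("owl:onProperty", [])
    fillers = node.get("owl:someValuesFrom", [])
    if len(props) != 1 or len(fillers) != 1:
        return None
    prop = props[0]
    filler = fillers[0]
    if not isinstance(prop, str) or not isinstance(filler, str):
        return None
    local = prop.split(":", 1)[-1]
    return Restriction(property=local, filler=filler)


def load_kb_turtle(path: str | Path) -> KnowledgeBase:
    text = Path(path).read_text(encoding="utf-8")
    triples = _Parser(_tokenize(text)).parse()

    kb = KnowledgeBase(properties={})
    declared_props: dict[str, Optional[str]] = {}

    # first pass: class/property declarations and the ontology header
    for s, p, o in triples:
        if p == "rdf:type" and o == "owl:Class" and isinstance(s, str):
            if s not in kb.concepts:
                kb.concepts[s] = Concept(id=s)
        elif p == "rdf:type" and o == "owl:ObjectProperty" and isinstance(s, str):
            declared_props.setdefault(s.split(":", 1)[-1], None)

    for s, p, o in triples:
        if not isinstance(s, str):
            _warn(f"skipping blank-node subject with predicate {p}")
            continue
        if p == "rdf:type":
            if o not in ("owl:Class", "owl:ObjectProperty", "owl:Ontology"):
                _warn(f"skipping rdf:type {o!r} for {s}")
            continue
        if s == ONTOLOGY_NODE or p in (
            "epo:signRoot", "epo:disorderRoot", "epo:anatomyRoot", "epo:technicalRoot",
        ):
            if p == "epo:signRoot":
                kb.sign_root = o
            elif p == "epo:disorderRoot":
                kb.disorder_root = o
            elif p == "epo:anatomyRoot":
                kb.anatomy_root = o
            elif p == "epo:technicalRoot":
                kb.technical_roots.append(o)
            else:
                _warn(f"skipping ontology-header predicate {p}")
            continue
        if p == "rdfs:subPropertyOf":
            child = s.split(":", 1)[-1]
            parent = o.split(":", 1)[-1] if isinstance(o, str) else None
            declared_props[child] = parent
            if parent is not None:
                declared_props.setdefault(parent, None)
            continue

        concept = kb.concepts.get(s)
        if concept is None and p.startswith(("skos:", "epo:", "rdfs:", "owl:")):
            concept = kb.concepts.setdefault(s, Concept(id=s))

        if p in ("skos:prefLabel", "skos:altLabel", "skos:definition"):
            if not (isinstance(o, tuple) and o[0] == "literal"):
                _warn(f"skipping non-literal {p} on {s}")
                continue
            _, txt, lang = o
            lt = LangText(text=txt, lang=lang or "en")
            target = {
                "skos:prefLabel": concept.pref_labels,
                "skos:altLabel": concept.alt_labels,
                "skos:definition": concept.definitions,
            }[p]
            target.append(lt)
        elif p == "skos:hiddenLabel":
            if isinstance(o, tuple) and o[0] == "literal":
                concept.hidden_label = o[1]
        elif p == "epo:FMAID":
            if isinstance(o, tuple) and o[0] == "literal":
                concept.fma_id = o[1]
        elif p == "epo:PMID":
            if isinstance(o, tuple) and o[0] == "literal":
                concept.pmids.append(o[1])
        elif p == "epo:ImagePath":
            if isinstance(o, tuple) and o[0] == "literal":
                concept.image_paths.append(o[1])
        elif p == "rdfs:subClassOf":
            if isinstance(o, str):
                kb.axioms.append(SubclassOf(s, o))
            else:
                r = _as_restriction(o)
                if r is None:
                    _warn(f"skipping unsupported subClassOf expression on {s}")
                else:
                    kb.axioms.append(SubclassOfRestriction(s, r))
        elif p == "owl:equivalentClass":
            definition = _as_definition(s, o)
            if definition is None:
                _warn(f"skipping unsupported equivalentClass expression on {s}")
            else:
                kb.axioms.append(definition)
        elif p == "owl:disjointWith":
            if isinstance(o, str):
                kb.axioms.append(Disjoint(frozenset({s, o})))
            else:
                _warn(f"skipping non-named disjointWith on {s}")
        else:
            _warn(f"skipping predicate {p} on {s}")

    kb.properties = declared_props or dict(DEFAULT_PROPERTIES)
    for prop, parent in DEFAULT_PROPERTIES.items():
        kb.properties.setdefault(prop, parent)

    derive_categories(kb)
    return kb


def _as_definition(cls: str, node: Any) -> Optional[EquivalentToDefinition]:
    if not isinstance(node, dict):
        return None
    inter = node.get("owl:intersectionOf", [])
    if len(inter) != 1 or not isinstance(inter[0], list):
        return None
    genus: Optional[str] = None
    restrictions: list[Restriction] = []
    for item in inter[0]:
        if isinstance(item, str):
            if genus is not None:
                return None  # more than one named conjunct
            genus = item
        else:
            r = _as_restriction(item)
            if r is None:
                return None
            restrictions.append(r)
    if genus is None or not restrictions:
        return None
    return EquivalentToDefinition(cls, genus, tuple(restrictions))

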
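"""Native JSON exchange format.

Lossless, deterministic (sorted keys, sorted concept order) and therefore
byte-identical across repeated saves of the same knowledge base.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .model import (
    Concept,
    Disjoint,
    EquivalentToDefinition,
    KBFormatError,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
)

FORMAT_VERSION = 1


def _langtexts(items: list[LangText]) -> list[dict[str, str]]:
    return [{"text": lt.text, "lang": lt.lang} for lt in sorted(items)]


def _concept_to_json(c: Concept) -> dict[str, Any]:
    return {
        "id": c.id,
        "pref_labels": _langtexts(c.pref_labels),
        "alt_labels": _langtexts(c.alt_labels),
        "definitions": _langtexts(c.definitions),
        "hidden_label": c.hidden_label,
        "fma_id": c.fma_id,
        "pmids": sorted(c.pmids),
        "image_paths": sorted(c.image_paths),
        "category": c.category,
    }


def _restriction_to_json(r: Restriction) -> dict[str, str]:
    return {"property": r.property, "filler": r.filler}


def _axiom_to_json(ax) -> dict[str, Any]:
    if isinstance(ax, SubclassOf):
        return {"kind": "subclass_of", "child": ax.child, "parent": ax.parent}
    if isinstance(ax, SubclassOfRestriction):
        return {
            "kind": "subclass_of_restriction",
            "child": ax.child,
            "restriction": _restriction_to_json(ax.restriction),
        }
    if isinstance(ax, EquivalentToDefinition):
        return {
            "kind": "equivalent_to_definition",
            "cls": ax.cls,
            "genus": ax.genus,
            "restrictions": [_restriction_to_json(r) for r in ax.restrictions],
        }
    if isinstance(ax, Disjoint):
        return {"kind": "disjoint", "members": sorted(ax.members)}
    raise TypeError(f"unknown axiom type: {ax!r}")


def kb_to_dict(kb: KnowledgeBase) -> dict[str, Any]:
    return {
        "format": "epokb",
        "version": FORMAT_VERSION,
        "roots": {
            "sign": kb.sign_root,
            "disorder": kb.disorder_root,
            "anatomy": kb.anatomy_root,
            "technical": list(kb.technical_roots),
        },
        "properties": {p: kb.properties[p] for p in sorted(kb.properties)},
        "concepts": [_concept_to_json(kb.concepts[cid]) for cid in sorted(kb.concepts)],
        "axioms": sorted(
            (_axiom_to_json(ax) for ax in kb.axioms), key=lambda d: json.dumps(d, sort_keys=True)
        ),
    }


def _langtext_from(obj: Any, where: str) -> LangText:
    try:
        return LangText(text=obj["text"], lang=obj["lang"])
    except (KeyError, TypeError, ValueError) as exc:
        raise KBFormatError(f"bad language-tagged text at {where}: {exc}") from exc


def _restriction_from(obj: Any, where: str) -> Restriction:
    try:
        return Restriction(property=obj["property"], filler=obj["filler"])
    except (KeyError, TypeError) as exc:
        raise KBFormatError(f"bad restriction at {where}: {exc}") from exc


def kb_from_dict(data: dict[str, Any]) -> KnowledgeBase:
    if not isinstance(data, dict) or data.get("format") != "epokb":
        raise KBFormatError("not an epokb JSON document (missing format marker)")
    if data.get("version") != FORMAT_VERSION:
        raise KBFormatError(f"unsupported format version {data.get('version')!r}")
    roots = data.get("roots") or {}
    kb = KnowledgeBase(
        properties=dict(data.get("properties") or {}),
        sign_root=roots.get("sign", ""),
        disorder_root=roots.get("disorder", ""),
        anatomy_root=roots.get("anatomy", ""),
        technical_roots=list(roots.get("technical", [])),
    )
    for i, cobj in enumerate(data.get("concepts", [])):
        where = f"concepts[{i}]"
        try:
            concept = Concept(
                id=cobj["id"],
                pref_labels=[_langtext_from(x, where) for x in cobj.get("pref_labels", [])],
                alt_labels=[_langtext_from(x, where) for x in cobj.get("alt_labels", [])],
                definitions=[_langtext_from(x, where) for x in cobj.get("definitions", [])],
                hidden_label=cobj.get("hidden_label"),
                fma_id=cobj.get("fma_id"),
                pmids=list(cobj.get("pmids", [])),
                image_paths=list(cobj.get("image_paths", [])),
                category=cobj.get("category", "other"),
            )
        except (KeyError, TypeError) as exc:
            raise KBFormatError(f"bad concept at {where}: {exc}") from exc
        if concept.id in kb.concepts:
            raise KBFormatError(f"duplicate concept id {concept.id!r} at {where}")
        kb.concepts[concept.id] = concept
    for i, aobj in enumerate(data.get("axioms", [])):
        where = f"axioms[{i}]"
        kind = aobj.get("kind")
        if kind == "subclass_of":
            kb.axioms.append(SubclassOf(aobj["child"], aobj["parent"]))
        elif kind == "subclass_of_restriction":
            kb.axioms.append(
                SubclassOfRestriction(aobj["child"], _restriction_from(aobj["restriction"], where))
            )
        elif kind == "equivalent_to_definition":
            kb.axioms.append(
                EquivalentToDefinition(
                    aobj["cls"],
                    aobj["genus"],
                    tuple(_restriction_from(r, where) for r in aobj["restrictions"]),
                )
            )
        elif kind == "disjoint":
            kb.axioms.append(Disjoint(frozenset(aobj["members"])))
        else:
            raise KBFormatError(f"unknown axiom kind {kind!r} at {where}")
    return kb


def save_kb_json(kb: KnowledgeBase, path: str | Path) -> None:
    text = json.dumps(kb_to_dict(kb), indent=2, sort_keys=True, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def load_kb_json(path: str | Path) -> KnowledgeBase:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise KBFormatError(f"JSON parse error at line {exc.lineno}: {exc.msg}") from exc
    return kb_from_dict(data)
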
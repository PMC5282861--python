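"""Knowledge-base data model, serialization, validation and search."""

from __future__ import annotations

from pathlib import Path

from .model import (
    CONFIGURED_LANGUAGES,
    DEFAULT_PROPERTIES,
    Axiom,
    Concept,
    Disjoint,
    EquivalentToDefinition,
    KBError,
    KBFormatError,
    KBValidationError,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
    assign_categories,
    kb_equal,
)
from .json_io import load_kb_json, save_kb_json, kb_to_dict, kb_from_dict
from .search import search_terms
from .turtle_io import TurtleSubsetWarning, load_kb_turtle, save_kb_turtle
from .validate import validate_kb

__all__ = [
    "CONFIGURED_LANGUAGES",
    "DEFAULT_PROPERTIES",
    "Axiom",
    "Concept",
    "Disjoint",
    "EquivalentToDefinition",
    "KBError",
    "KBFormatError",
    "KBValidationError",
    "KnowledgeBase",
    "LangText",
    "Restriction",
    "SubclassOf",
    "SubclassOfRestriction",
    "TurtleSubsetWarning",
    "assign_categories",
    "kb_equal",
    "kb_from_dict",
    "kb_to_dict",
    "load_kb",
    "load_kb_json",
    "load_kb_turtle",
    "save_kb",
    "save_kb_json",
    "save_kb_turtle",
    "search_terms",
    "validate_kb",
]


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".ttl", ".turtle"):
        return "turtle"
    return "json"


def load_kb(path: str | Path, format: str | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base (``json`` or ``turtle``)."""
    fmt = _detect_format(path, format)
    if fmt == "json":
        kb = load_kb_json(path)
    elif fmt == "turtle":
        kb = load_kb_turtle(path)
    else:
        raise KBFormatError(f"unknown format {fmt!r}")
    issues = validate_kb(kb)
    if issues:
        raise KBValidationError(issues)
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path, format: str | None = None) -> None:
    """Serialize ``kb`` deterministically (``json`` or ``turtle``)."""
    fmt = _detect_format(path, format)
    if fmt == "json":
        save_kb_json(kb, path)
    elif fmt == "turtle":
        save_kb_turtle(kb, path)
    else:
        raise KBFormatError(f"unknown format {fmt!r}")
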
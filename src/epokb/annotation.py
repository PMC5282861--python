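"""Annotation sessions: images × observers × selected concepts, plus an
optional report-derived gold standard.

Annotations have set semantics per (image, observer): re-selecting a
concept is idempotent.  The JSON exchange format is documented in
``docs/session.schema.json`` and validated structurally on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

from .kb_core.model import KBError, KnowledgeBase
from .reasoner import SubsumptionClosure, compute_closure

COHORTS = ("common", "specific")
GRADES = ("senior", "senior_registrar", "registrar")


class SessionFormatError(KBError):
    """Raised with a JSON-pointer-style path when a session file is invalid."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    case_id: str
    cohort: str = "common"


@dataclass(frozen=True)
class ObserverID:
    value: str
    grade: Optional[str] = None


@dataclass(frozen=True, order=True)
class Annotation:
    image_id: str
    observer: str
    concept: str


@dataclass
class AnnotationSession:
    kb: Optional[KnowledgeBase]
    images: list[ImageRecord] = field(default_factory=list)
    observers: list[ObserverID] = field(default_factory=list)
    annotations: set[Annotation] = field(default_factory=set)
    gold: Optional[dict[str, frozenset[str]]] = None

    def observer_count(self) -> int:
        return len(self.observers)

    def image_ids(self, cohort: Optional[str] = None) -> list[str]:
        return [im.image_id for im in self.images if cohort is None or im.cohort == cohort]

    def annotations_for(self, image_id: str, observer: str) -> frozenset[str]:
        return frozenset(
            a.concept for a in self.annotations
            if a.image_id == image_id and a.observer == observer
        )

    def validate(self) -> list[str]:
        """Referential-integrity issues (empty list when clean)."""
        issues: list[str] = []
        seen_images: set[str] = set()
        for im in self.images:
            if im.image_id in seen_images:
                issues.append(f"duplicate image id {im.image_id!r}")
            seen_images.add(im.image_id)
            if im.cohort not in COHORTS:
                issues.append(f"image {im.image_id!r}: unknown cohort {im.cohort!r}")
        observers = {o.value for o in self.observers}
        if len(observers) != len(self.observers):
            issues.append("duplicate observer identifiers")
        for o in self.observers:
            if o.grade is not None and o.grade not in GRADES:
                issues.append(f"observer {o.value!r}: unknown grade {o.grade!r}")
        for a in sorted(self.annotations):
            if a.image_id not in seen_images:
                issues.append(f"annotation references unknown image {a.image_id!r}")
            if a.observer not in observers:
                issues.append(f"annotation references unknown observer {a.observer!r}")
            if self.kb is not None and a.concept not in self.kb.concepts:
                issues.append(f"annotation references unknown concept {a.concept!r}")
        if self.gold is not None:
            for image_id, signs in sorted(self.gold.items()):
                if image_id not in seen_images:
                    issues.append(f"gold standard references unknown image {image_id!r}")
                if self.kb is not None:
                    for s in sorted(signs):
                        if s not in self.kb.concepts:
                            issues.append(f"gold standard references unknown concept {s!r}")
        return issues


# ---------------------------------------------------------------------------
# serialization

def session_to_dict(session: AnnotationSession) -> dict[str, Any]:
    data: dict[str, Any] = {
        "format": "epokb-session",
        "version": 1,
        "images": [
            {"image_id": im.image_id, "case_id": im.case_id, "cohort": im.cohort}
            for im in sorted(session.images, key=lambda im: im.image_id)
        ],
        "observers": [
            {"id": o.value, "grade": o.grade}
            for o in sorted(session.observers, key=lambda o: o.value)
        ],
        "annotations": [
            {"image_id": a.image_id, "observer": a.observer, "concept": a.concept}
            for a in sorted(session.annotations)
        ],
    }
    if session.gold is not None:
        data["gold"] = {img: sorted(signs) for img, signs in sorted(session.gold.items())}
    return data


def _require(obj: Any, key: str, typ, pointer: str) -> Any:
    if not isinstance(obj, dict) or key not in obj:
        raise SessionFormatError(pointer, f"missing required key {key!r}")
    val = obj[key]
    if not isinstance(val, typ):
        raise SessionFormatError(f"{pointer}/{key}", f"expected {typ.__name__}")
    return val


def session_from_dict(
    data: dict[str, Any], kb: Optional[KnowledgeBase] = None
) -> AnnotationSession:
    if not isinstance(data, dict) or data.get("format") != "epokb-session":
        raise SessionFormatError("", "not an epokb session document")
    session = AnnotationSession(kb=kb)
    for i, obj in enumerate(_require(data, "images", list, "")):
        ptr = f"/images/{i}"
        session.images.append(
            ImageRecord(
                image_id=_require(obj, "image_id", str, ptr),
                case_id=_require(obj, "case_id", str, ptr),
                cohort=obj.get("cohort", "common"),
            )
        )
    for i, obj in enumerate(_require(data, "observers", list, "")):
        ptr = f"/observers/{i}"
        session.observers.append(
            ObserverID(value=_require(obj, "id", str, ptr), grade=obj.get("grade"))
        )
    for i, obj in enumerate(_require(data, "annotations", list, "")):
        ptr = f"/annotations/{i}"
        session.annotations.add(
            Annotation(
                image_id=_require(obj, "image_id", str, ptr),
                observer=_require(obj, "observer", str, ptr),
                concept=_require(obj, "concept", str, ptr),
            )
        )
    if "gold" in data:
        gold_obj = _require(data, "gold", dict, "")
        session.gold = {
            img: frozenset(signs) for img, signs in gold_obj.items()
        }
    issues = session.validate()
    if issues:
        raise SessionFormatError("", "; ".join(issues))
    return session


def save_session(session: AnnotationSession, path: str | Path) -> None:
    text = json.dumps(session_to_dict(session), indent=2, sort_keys=True, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def load_session(path: str | Path, kb: Optional[KnowledgeBase] = None) -> AnnotationSession:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SessionFormatError("", f"JSON parse error at line {exc.lineno}: {exc.msg}")
    return session_from_dict(data, kb=kb)


# ---------------------------------------------------------------------------
# annotation matrix

def _sign_ids(session: AnnotationSession, closure: Optional[SubsumptionClosure]) -> set[str]:
    if session.kb is None:
        return {a.concept for a in session.annotations}
    if closure is None:
        closure = compute_closure(session.kb)
    root = session.kb.sign_root
    return {c for c in session.kb.concepts if root in closure.of(c)}


def annotation_matrix(
    session: AnnotationSession,
    sign: str,
    cohort: Optional[str] = None,
    closure: Optional[SubsumptionClosure] = None,
) -> list[tuple[str, int, int]]:
    """Rows ``(image_id, k, x)`` for images where ≥1 observer marked ``sign``.

    ``k`` is the number of annotating observers, ``x`` the panel size.
    Invariant to annotation order and duplicates (set semantics).
    """
    if session.kb is not None:
        if closure is None:
            closure = compute_closure(session.kb)
        root = session.kb.sign_root
        if sign not in session.kb.concepts or root not in closure.of(sign):
            raise KBError(f"{sign} is not a sign concept")
    x = session.observer_count()
    counts: dict[str, set[str]] = {}
    wanted = set(session.image_ids(cohort))
    for a in session.annotations:
        if a.concept == sign and a.image_id in wanted:
            counts.setdefault(a.image_id, set()).add(a.observer)
    return [(img, len(obs), x) for img, obs in sorted(counts.items())]


def observed_sign_sets(
    session: AnnotationSession,
    cohort: Optional[str] = None,
    signs_only: bool = True,
    closure: Optional[SubsumptionClosure] = None,
) -> dict[tuple[str, str], frozenset[str]]:
    """Non-empty observed sets per (image, observer) unit.

    With ``signs_only`` the sets are restricted to sign-category concepts
    (annotations of anatomy/technical elements are legitimate but do not
    enter precision against the sign gold standard).
    """
    signs = _sign_ids(session, closure) if signs_only else None
    wanted = set(session.image_ids(cohort))
    units: dict[tuple[str, str], set[str]] = {}
    for a in session.annotations:
        if a.image_id not in wanted:
            continue
        if signs is not None and a.concept not in signs:
            continue
        units.setdefault((a.image_id, a.observer), set()).add(a.concept)
    return {unit: frozenset(s) for unit, s in units.items() if s}


def annotated_signs(
    session: AnnotationSession,
    cohort: Optional[str] = None,
    closure: Optional[SubsumptionClosure] = None,
) -> list[str]:
    """Distinct sign concepts annotated in the cohort, sorted."""
    signs = _sign_ids(session, closure)
    wanted = set(session.image_ids(cohort))
    return sorted(
        {a.concept for a in session.annotations if a.image_id in wanted and a.concept in signs}
    )
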
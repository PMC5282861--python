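"""Case-insensitive label search with exact > prefix > substring ranking."""

from __future__ import annotations

from .model import CONFIGURED_LANGUAGES, KBError, KnowledgeBase


def search_terms(
    kb: KnowledgeBase, query: str, lang: str = "en", limit: int = 10
) -> list[str]:
    """Return up to ``limit`` concept ids matching ``query`` in ``lang``.

    Exact preferred-label matches rank first, then prefix matches, then
    substring matches; ties break on concept id.  Empty queries match
    nothing.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    if lang not in CONFIGURED_LANGUAGES:
        raise KBError(
            f"unknown language {lang!r}; configured languages: "
            + ", ".join(CONFIGURED_LANGUAGES)
        )
    q = query.strip().lower()
    if not q:
        return []

    ranked: list[tuple[int, str]] = []
    for cid in sorted(kb.concepts):
        c = kb.concepts[cid]
        pref = c.pref_label(lang)
        labels = [lbl.lower() for lbl in c.labels(lang)]
        if not labels:
            continue
        if pref is not None and pref.lower() == q:
            rank = 0
        elif any(lbl.startswith(q) for lbl in labels):
            rank = 1
        elif any(q in lbl for lbl in labels):
            rank = 2
        else:
            continue
        ranked.append((rank, cid))
    ranked.sort()
    return [cid for _, cid in ranked[:limit]]
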
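"""Published counts from the reference six-observer annotation study.

These are the raw concordant-pair / discordant-pair / image counts for the
24 signs evaluated on the five common clinical cases, bundled as example
data for the agreement statistics.  One row's counts were reconstructed
from its printed proportion (13.33%) and confidence interval ([1.17,
25.50]), which uniquely determine 4 agreements out of 30 pairs over 2
images; the published count column for that row is typographically
corrupt.
"""

from __future__ import annotations

#: (sign label, agreements, disagreements, images)
AGREEMENT_COUNTS: tuple[tuple[str, int, int, int], ...] = (
    ("endometrial trilaminar pattern", 48, 12, 4),
    ("adnexal mass distinct from ovary", 143, 37, 12),
    ("embryo visible outside the uterine cavity", 45, 15, 4),
    ("gestational sac outside the uterine cavity", 226, 104, 22),
    ("adnexal mass adjacent to ovary", 122, 58, 12),
    ("gestational sac or trophoblast in a myometrial defect in previous caesarean section scar pregnancy site", 119, 76, 13),
    ("adnexal mass and corpus luteum at the same side", 82, 53, 9),
    ("adnexal rounded hyperechoic mass", 63, 57, 8),
    ("ring of fire sign", 39, 36, 5),
    ("yolk sac visible outside the uterine cavity", 64, 71, 9),
    ("adnexal mass as gestational sac with yolk sac", 22, 38, 4),
    ("caesarean section scar pregnancy peritrophoblastic blood flow", 19, 41, 4),
    ("intact endometrial midline echo", 14, 31, 3),
    ("tubal ring sign", 45, 120, 11),
    ("tubal ring without central identifying feature", 24, 66, 6),
    ("trophoblast visible outside the uterine cavity", 110, 325, 29),
    ("anterior distortion of uterus serosa", 24, 96, 8),
    ("smaller trophoblastic border distance to the anterior uterine serosa", 33, 162, 13),
    ("ectopic pregnancy wall more echogenic than corpus luteum wall", 21, 114, 9),
    ("fluid collection located centrally within the uterine cavity", 4, 26, 2),
    ("non intact endometrial midline echo", 4, 41, 3),
    ("gestational sac or trophoblast located at the level of internal cervical os", 10, 125, 9),
    ("gestational sac inside anterior myometrium and uterine cavity", 1, 44, 3),
    ("gestational sac located eccentricaly from uterine cavity", 1, 149, 10),
)

#: Observer panel size in the reference study.
PANEL_SIZE = 6

#: Worked example: 5 of 6 observers marked a sign on one image.
WORKED_EXAMPLE_K = 5

#: Common-cohort annotation totals: 58 of 841 annotations were made by a
#: single observer.
SINGLE_OBSERVER_ANNOTATIONS = 58
COMMON_COHORT_ANNOTATIONS = 841


def _k_vector(agreements: int, images: int, panel: int = PANEL_SIZE) -> list[int]:
    """Decompose a concordant-pair count into per-image annotator counts.

    Finds k_1..k_m with 1 <= k_i <= panel and sum C(k_i, 2) == agreements;
    exists for every published row (trial counts are multiples of the
    per-image pair count).
    """
    pair_counts = [(k, k * (k - 1) // 2) for k in range(panel, 0, -1)]

    def solve(remaining: int, slots: int) -> list[int] | None:
        if slots == 0:
            return [] if remaining == 0 else None
        for k, pairs in pair_counts:
            if pairs > remaining:
                continue
            # bounds prune: the other slots must be able to absorb the rest
            max_rest = (slots - 1) * pair_counts[0][1]
            if remaining - pairs > max_rest:
                continue
            rest = solve(remaining - pairs, slots - 1)
            if rest is not None:
                return [k] + rest
        return None

    ks = solve(agreements, images)
    if ks is None:
        raise ValueError(
            f"no per-image decomposition of {agreements} agreements over {images} images"
        )
    return ks


def build_reference_session(kb):
    """Annotation session reproducing the published per-sign agreement
    counts end to end (six observers, common cohort).

    Each sign's concordant-pair count is decomposed into per-image
    annotator counts, so running the agreement table over this session
    yields exactly the published (agreements, disagreements, images)
    triples per sign.
    """
    from ..annotation import Annotation, AnnotationSession, ImageRecord, ObserverID
    from .mini_epo import concept_id

    session = AnnotationSession(kb=kb)
    session.observers = [ObserverID(f"obs{i + 1}") for i in range(PANEL_SIZE)]
    n_images = max(images for _, _, _, images in AGREEMENT_COUNTS)
    session.images = [
        ImageRecord(image_id=f"img{i + 1:02d}", case_id=f"case{i % 5 + 1}",
                    cohort="common")
        for i in range(n_images)
    ]
    for label, agreements, _disagreements, images in AGREEMENT_COUNTS:
        sign = concept_id(label)
        for img_index, k in enumerate(_k_vector(agreements, images)):
            image_id = session.images[img_index].image_id
            for obs in session.observers[:k]:
                session.annotations.add(Annotation(image_id, obs.value, sign))
    return session


def build_single_observer_share_session(kb):
    """Session realizing the published common-cohort annotation totals:
    58 of 841 annotation records contributed by exactly one observer."""
    from ..annotation import Annotation, AnnotationSession, ImageRecord, ObserverID
    from .mini_epo import EVALUATED_SIGN_LABELS, concept_id

    session = AnnotationSession(kb=kb)
    session.observers = [ObserverID(f"obs{i + 1}") for i in range(PANEL_SIZE)]
    signs = [concept_id(l) for l in EVALUATED_SIGN_LABELS]
    multi = COMMON_COHORT_ANNOTATIONS - SINGLE_OBSERVER_ANNOTATIONS  # 783 = 261 * 3
    assert multi % 3 == 0
    pairs_needed = SINGLE_OBSERVER_ANNOTATIONS + multi // 3
    n_images = -(-pairs_needed // len(signs))
    session.images = [
        ImageRecord(image_id=f"simg{i + 1:02d}", case_id=f"case{i % 5 + 1}",
                    cohort="common")
        for i in range(n_images)
    ]
    slots = [(im.image_id, s) for im in session.images for s in signs]
    for image_id, sign in slots[:SINGLE_OBSERVER_ANNOTATIONS]:
        session.annotations.add(Annotation(image_id, "obs1", sign))
    for image_id, sign in slots[SINGLE_OBSERVER_ANNOTATIONS:pairs_needed]:
        for obs in ("obs1", "obs2", "obs3"):
            session.annotations.add(Annotation(image_id, obs, sign))
    return session
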
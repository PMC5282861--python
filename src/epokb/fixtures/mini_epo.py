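"""Deterministic construction of the bundled mini knowledge base.

The fixture models the published slice of the ectopic-pregnancy domain:
the 24 evaluated sign labels plus the interstitial line sign, the four
implantation-site disorder types (with tubal subtypes), the pelvic anatomy
involved, the three technical-element hierarchies, and the four defined
sign categories.  The ring-of-fire sign carries the full relation set
(suggests / hasLocation / requiresRoute / requiresMode / requiresView) and
its reference-image provenance.

Identifiers are stable hashes of the English preferred label so tests can
reference concepts symbolically; the sign and disorder roots use the two
well-known identifiers that appear in the application's query constants.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from ..kb_core.model import (
    derive_categories,
    Concept,
    Disjoint,
    EquivalentToDefinition,
    KnowledgeBase,
    LangText,
    Restriction,
    SubclassOf,
    SubclassOfRestriction,
)

SIGN_ROOT_ID = "epo:OPPIO_0000189"
DISORDER_ROOT_ID = "epo:OPPIO_c000016"

#: The 24 evaluated sign labels (agreement table order).
EVALUATED_SIGN_LABELS = (
    "endometrial trilaminar pattern",
    "adnexal mass distinct from ovary",
    "embryo visible outside the uterine cavity",
    "gestational sac outside the uterine cavity",
    "adnexal mass adjacent to ovary",
    "gestational sac or trophoblast in a myometrial defect in previous caesarean section scar pregnancy site",
    "adnexal mass and corpus luteum at the same side",
    "adnexal rounded hyperechoic mass",
    "ring of fire sign",
    "yolk sac visible outside the uterine cavity",
    "adnexal mass as gestational sac with yolk sac",
    "caesarean section scar pregnancy peritrophoblastic blood flow",
    "intact endometrial midline echo",
    "tubal ring sign",
    "tubal ring without central identifying feature",
    "trophoblast visible outside the uterine cavity",
    "anterior distortion of uterus serosa",
    "smaller trophoblastic border distance to the anterior uterine serosa",
    "ectopic pregnancy wall more echogenic than corpus luteum wall",
    "fluid collection located centrally within the uterine cavity",
    "non intact endometrial midline echo",
    "gestational sac or trophoblast located at the level of internal cervical os",
    "gestational sac inside anterior myometrium and uterine cavity",
    "gestational sac located eccentricaly from uterine cavity",
)

RING_OF_FIRE_PMID = "18936028"


def concept_id(label: str) -> str:
    """Deterministic identifier for a fixture concept (stable label hash)."""
    if label == "ultrasound sign":
        return SIGN_ROOT_ID
    if label == "ectopic pregnancy":
        return DISORDER_ROOT_ID
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).hexdigest()
    return "epo:OPPIO_" + digest[:7]


@dataclass(frozen=True)
class MiniEpoManifest:
    """Expected inventory of the fixture; tests compare field-for-field."""

    concept_count: int
    sign_count: int           # concepts under the sign root (root excluded)
    disorder_count: int       # concepts under the disorder root (root excluded)
    anatomy_count: int
    technical_count: int
    defined_class_count: int
    subclass_axiom_count: int
    restriction_axiom_count: int
    disjoint_axiom_count: int
    pmid_annotation_count: int
    image_annotation_count: int
    suggests_assertion_count: int
    top_level_disorders: tuple[str, ...] = field(default=())
    cervical_pregnancy_signs: tuple[str, ...] = field(default=())


class _Builder:
    def __init__(self) -> None:
        self.kb = KnowledgeBase()

    def concept(self, label: str, parents: tuple[str, ...] = (), *,
                definition: str | None = None, fr: str | None = None,
                alt: tuple[str, ...] = (), fma: str | None = None) -> str:
        cid = concept_id(label)
        c = Concept(id=cid, pref_labels=[LangText(label, "en")],
                    hidden_label=cid.split(":", 1)[1])
        if fr:
            c.pref_labels.append(LangText(fr, "fr"))
        for a in alt:
            c.alt_labels.append(LangText(a, "en"))
        if definition:
            c.definitions.append(LangText(definition, "en"))
        c.fma_id = fma
        self.kb.add_concept(c)
        for p in parents:
            self.kb.axioms.append(SubclassOf(cid, concept_id(p)))
        return cid

    def sign(self, label: str, parent: str = "imaging sign", **kw) -> str:
        definition = kw.pop(
            "definition",
            f"Ultrasound feature: {label}, as seen on an ectopic pregnancy scan.",
        )
        return self.concept(label, (parent,), definition=definition, **kw)

    def restrict(self, child_label: str, prop: str, filler_label: str) -> None:
        self.kb.axioms.append(
            SubclassOfRestriction(
                concept_id(child_label),
                Restriction(prop, concept_id(filler_label)),
            )
        )

    def define(self, label: str, genus_label: str,
               *restrictions: tuple[str, str], definition: str) -> str:
        cid = concept_id(label)
        c = Concept(id=cid, pref_labels=[LangText(label, "en")],
                    definitions=[LangText(definition, "en")],
                    hidden_label=cid.split(":", 1)[1])
        self.kb.add_concept(c)
        self.kb.axioms.append(
            EquivalentToDefinition(
                cid,
                concept_id(genus_label),
                tuple(Restriction(p, concept_id(f)) for p, f in restrictions),
            )
        )
        return cid


def build_mini_epo() -> KnowledgeBase:
    b = _Builder()
    kb = b.kb

    # category roots -----------------------------------------------------
    kb.sign_root = b.concept(
        "ultrasound sign",
        definition="A visually recognizable feature of an ultrasound image.",
    )
    kb.disorder_root = b.concept(
        "ectopic pregnancy",
        definition="Implantation of a gestational sac outside the endometrial cavity.",
        fr="grossesse extra-utérine",
    )
    kb.anatomy_root = b.concept("anatomical structure")
    kb.technical_roots = [
        b.concept("examination route"),
        b.concept("examination mode"),
        b.concept("echographic view"),
    ]

    # disorders ----------------------------------------------------------
    b.concept("tubal pregnancy", ("ectopic pregnancy",),
              definition="Ectopic pregnancy implanted in the fallopian tube.",
              fr="grossesse tubaire")
    b.concept("interstitial pregnancy", ("ectopic pregnancy",),
              definition="Ectopic pregnancy implanted in the interstitial portion of the tube.")
    b.concept("cervical pregnancy", ("ectopic pregnancy",),
              definition="Ectopic pregnancy implanted in the cervical canal.")
    b.concept("cesarean section scar pregnancy", ("ectopic pregnancy",),
              definition="Ectopic pregnancy implanted in a previous cesarean section scar.",
              alt=("c-section scar pregnancy",))
    b.concept("ampullar pregnancy", ("tubal pregnancy",),
              definition="Tubal pregnancy implanted in the ampulla.")
    b.concept("isthmic pregnancy", ("tubal pregnancy",),
              definition="Tubal pregnancy implanted in the tubal isthmus.")
    b.concept("fimbrial pregnancy", ("tubal pregnancy",),
              definition="Tubal pregnancy implanted in the fimbrial portion.")
    kb.axioms.append(
        Disjoint(frozenset({
            concept_id("tubal pregnancy"),
            concept_id("interstitial pregnancy"),
            concept_id("cervical pregnancy"),
            concept_id("cesarean section scar pregnancy"),
        }))
    )

    # anatomy ------------------------------------------------------------
    b.concept("uterus", ("anatomical structure",), fma="17558")
    b.concept("uterine tube", ("anatomical structure",), fma="18245")
    b.concept("zone of uterine tube", ("uterine tube",))
    b.concept("ampulla", ("zone of uterine tube",))
    b.concept("tubal isthmus", ("zone of uterine tube",))
    b.concept("fimbrial portion", ("zone of uterine tube",))
    b.concept("ovary", ("anatomical structure",), fma="7209")
    b.concept("gestational sac", ("anatomical structure",))
    b.concept("trophoblast", ("anatomical structure",))

    # technical elements -------------------------------------------------
    b.concept("vaginal route", ("examination route",))
    b.concept("abdominal route", ("examination route",))
    b.concept("color Doppler mode", ("examination mode",))
    b.concept("2D mode", ("examination mode",))
    # 2D colour Doppler specialises both modes (multi-parent DAG case)
    b.concept("color Doppler mode (2D)", ("color Doppler mode", "2D mode"))
    b.concept("adnexal area view", ("echographic view",))
    b.concept("longitudinal view of the uterus", ("echographic view",))

    # signs --------------------------------------------------------------
    b.sign("imaging sign", parent="ultrasound sign")
    for label in EVALUATED_SIGN_LABELS:
        if label == "tubal ring without central identifying feature":
            continue  # handled below: specialises the tubal ring sign
        b.sign(label)
    b.sign("tubal ring without central identifying feature",
           parent="tubal ring sign")
    b.sign("interstitial line sign")

    rof = kb.concepts[concept_id("ring of fire sign")]
    rof.pref_labels.append(LangText("signe de l'anneau de feu", "fr"))
    rof.alt_labels.append(LangText("vascular ring", "en"))
    rof.pmids.append(RING_OF_FIRE_PMID)
    rof.image_paths.append("images/ring_of_fire_1.png")
    kb.concepts[concept_id("tubal ring sign")].image_paths.append(
        "images/tubal_ring_1.png"
    )

    # defined sign categories -------------------------------------------
    b.define("color Doppler sign", "imaging sign",
             ("requiresMode", "color Doppler mode"),
             definition="An imaging sign visible using the color Doppler mode.")
    b.define("2D ultrasound sign", "imaging sign",
             ("requiresMode", "2D mode"),
             definition="An imaging sign visible using the 2D ultrasound mode.")
    b.define("tubal pregnancy sign", "imaging sign",
             ("suggests", "tubal pregnancy"),
             definition="An imaging sign suggesting a tubal pregnancy.")
    b.define("c-section scar pregnancy sign", "imaging sign",
             ("suggests", "cesarean section scar pregnancy"),
             definition="An imaging sign suggesting a cesarean section scar pregnancy.")

    # sign-centric relations (asserted at the most general level) --------
    b.restrict("ring of fire sign", "suggests", "tubal pregnancy")
    b.restrict("ring of fire sign", "hasLocation", "ampulla")
    b.restrict("ring of fire sign", "hasLocation", "tubal isthmus")
    b.restrict("ring of fire sign", "hasLocation", "fimbrial portion")
    b.restrict("ring of fire sign", "requiresRoute", "vaginal route")
    b.restrict("ring of fire sign", "requiresMode", "color Doppler mode (2D)")
    b.restrict("ring of fire sign", "requiresView", "adnexal area view")

    b.restrict("tubal ring sign", "suggests", "tubal pregnancy")
    b.restrict("tubal ring sign", "hasLocation", "uterine tube")
    b.restrict("tubal ring sign", "requiresView", "adnexal area view")
    b.restrict("tubal ring sign", "requiresMode", "2D mode")

    b.restrict(
        "gestational sac or trophoblast in a myometrial defect in previous caesarean section scar pregnancy site",
        "suggests", "cesarean section scar pregnancy")
    b.restrict("caesarean section scar pregnancy peritrophoblastic blood flow",
               "suggests", "cesarean section scar pregnancy")
    b.restrict("caesarean section scar pregnancy peritrophoblastic blood flow",
               "requiresMode", "color Doppler mode")
    b.restrict("interstitial line sign", "suggests", "interstitial pregnancy")
    b.restrict(
        "gestational sac or trophoblast located at the level of internal cervical os",
        "suggests", "cervical pregnancy")
    b.restrict(
        "gestational sac or trophoblast located at the level of internal cervical os",
        "requiresView", "longitudinal view of the uterus")
    b.restrict("gestational sac located eccentricaly from uterine cavity",
               "hasLocation", "uterus")

    derive_categories(kb)
    return kb


def mini_epo_manifest() -> MiniEpoManifest:
    """Ground-truth inventory of :func:`build_mini_epo`."""
    return MiniEpoManifest(
        concept_count=59,
        sign_count=30,          # 24 evaluated + interstitial line + imaging sign + 4 defined
        disorder_count=7,
        anatomy_count=9,
        technical_count=7,
        defined_class_count=4,
        subclass_axiom_count=50,
        restriction_axiom_count=18,
        disjoint_axiom_count=1,
        pmid_annotation_count=1,
        image_annotation_count=2,
        suggests_assertion_count=6,
        top_level_disorders=tuple(sorted(
            concept_id(l) for l in (
                "tubal pregnancy", "interstitial pregnancy",
                "cervical pregnancy", "cesarean section scar pregnancy",
            )
        )),
        cervical_pregnancy_signs=(
            concept_id("gestational sac or trophoblast located at the level of internal cervical os"),
        ),
    )
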
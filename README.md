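# epokb

A sign-centric knowledge base engine for ultrasound image annotation:

* **kb_core** — data model for concepts (SKOS-style labels/definitions,
  PMID / image-path / FMA annotations), a fixed object-property hierarchy
  (`suggests`, `hasLocation`, `requires` ⊒ `requiresRoute` / `requiresMode` /
  `requiresView`), axioms (subsumption, existential restrictions, defined
  classes, disjointness), validation, label search, and two serializations:
  a native JSON exchange format and a restricted Turtle/OWL subset.
* **reasoner** — EL-style inference: reflexive-transitive subsumption
  closure, defined-class classification (genus + existential restrictions,
  with subproperty matching, iterated to fixpoint), materialization of
  inherited sign relations with provenance, and disjointness checking.
* **suggestion** — the query layer: suggest disorder types for selected
  signs (at the granularity of direct children of the disorder root),
  suggest further signs for selected types, per-sign relation profiles,
  reference-image lookup, and competency queries (implantation sites,
  structures visible in a view).
* **annotation** — JSON annotation sessions (images × observers × selected
  concepts) with an optional per-image gold standard and the per-sign
  annotation matrix (schema in `docs/session.schema.json`).
* **metrics** — multi-observer proportion of agreement (concordant-positive
  pairs / all pairs) with Wald 95% CI, per-sign and pooled table rendering,
  and micro-averaged information-retrieval precision.
* **fixtures** — a deterministic mini knowledge base (24 evaluated signs +
  the interstitial line sign, four implantation-site disorder types, pelvic
  anatomy, technical-element hierarchies, four defined sign categories),
  published reference-study counts, and seeded synthetic generators for
  knowledge bases (with brute-force-oracle ground truth) and annotation
  sessions.

## CLI

```sh
epokb fixture mini-epo --out kb.json        # build the bundled fixture KB
epokb validate kb.json                      # structural validation
epokb convert kb.json kb.ttl                # JSON <-> Turtle (by extension)
epokb search kb.json --query "ring of f" --lang en
epokb infer kb.json --out relations.csv     # materialized relations + provenance
epokb check kb.json                         # disjointness consistency (exit code)
epokb suggest --kb kb.json --signs epo:OPPIO_... --json
epokb ask implantation-sites --kb kb.json
epokb sim kb --n 200 --seed 1 --out syn.json
epokb sim session --kb kb.json --images 200 --observers 6 --sens 0.9 --fp 0.05 \
    --seed 13 --out session.json
epokb session validate session.json --kb kb.json
epokb session matrix session.json --kb kb.json --sign epo:OPPIO_...
epokb eval agreement --session session.json --kb kb.json
epokb eval precision --session session.json --kb kb.json
```

## Notes on the agreement CI renderings

`AgreementRow.percent()` rounds the exact Wald interval; this reproduces
pooled totals. `AgreementRow.percent_prerounded()` recomputes the interval
from the 2-decimal rounded percentage, which is the convention evident in
published per-sign tables; both are exposed and tested.
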
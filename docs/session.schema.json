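{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/epokb/session.schema.json",
  "title": "epokb annotation session",
  "type": "object",
  "required": ["format", "version", "images", "observers", "annotations"],
  "properties": {
    "format": {"const": "epokb-session"},
    "version": {"const": 1},
    "images": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "case_id"],
        "properties": {
          "image_id": {"type": "string", "minLength": 1},
          "case_id": {"type": "string", "minLength": 1},
          "cohort": {"enum": ["common", "specific"]}
        }
      }
    },
    "observers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "grade": {
            "anyOf": [
              {"enum": ["senior", "senior_registrar", "registrar"]},
              {"type": "null"}
            ]
          }
        }
      }
    },
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "observer", "concept"],
        "properties": {
          "image_id": {"type": "string"},
          "observer": {"type": "string"},
          "concept": {"type": "string"}
        }
      }
    },
    "gold": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {"type": "string"}
      }
    }
  }
}
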
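{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/crseligible/ruleset.schema.json",
  "title": "crseligible rule-set document",
  "description": "Declarative biologic-indication criterion tree. Leaves compare a numeric patient-record field against a cutoff (>=) or lift a boolean field; connectives are Kleene all_of / any_of and the at_least (k-of-n) operator.",
  "type": "object",
  "required": ["name", "tree"],
  "additionalProperties": false,
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "thresholds": {
      "type": "object",
      "description": "Informational threshold table; evaluation reads cutoffs from the tree leaves.",
      "additionalProperties": {
        "oneOf": [
          {"type": "number"},
          {"type": "array", "items": {"type": "integer"}, "minItems": 2, "maxItems": 2}
        ]
      }
    },
    "tree": {"$ref": "#/definitions/node"}
  },
  "definitions": {
    "node": {
      "oneOf": [
        {
          "type": "object",
          "required": ["type", "id", "field", "cutoff"],
          "additionalProperties": false,
          "properties": {
            "type": {"const": "threshold"},
            "id": {"type": "string", "minLength": 1},
            "field": {"type": "string"},
            "cutoff": {"type": "number"}
          }
        },
        {
          "type": "object",
          "required": ["type", "id", "field"],
          "additionalProperties": false,
          "properties": {
            "type": {"const": "flag"},
            "id": {"type": "string", "minLength": 1},
            "field": {"type": "string"}
          }
        },
        {
          "type": "object",
          "required": ["type", "id", "children"],
          "additionalProperties": false,
          "properties": {
            "type": {"enum": ["all_of", "any_of"]},
            "id": {"type": "string", "minLength": 1},
            "children": {
              "type": "array",
              "minItems": 1,
              "items": {"$ref": "#/definitions/node"}
            }
          }
        },
        {
          "type": "object",
          "required": ["type", "id", "k", "children"],
          "additionalProperties": false,
          "properties": {
            "type": {"const": "at_least"},
            "id": {"type": "string", "minLength": 1},
            "k": {"type": "integer", "minimum": 1},
            "children": {
              "type": "array",
              "minItems": 1,
              "items": {"$ref": "#/definitions/node"}
            }
          }
        }
      ]
    }
  }
}
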
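{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "trialcube design document",
  "description": "Structured text serialization of a master-protocol design space (extension .design.json). schema_version 1.0.",
  "type": "object",
  "required": ["schema_version", "space"],
  "properties": {
    "schema_version": { "const": "1.0" },
    "metadata": { "type": "object" },
    "space": {
      "type": "object",
      "required": ["axes"],
      "properties": {
        "axes": {
          "type": "array",
          "minItems": 2,
          "items": {
            "type": "object",
            "required": ["name", "role", "elements"],
            "properties": {
              "name": { "type": "string" },
              "role": { "enum": ["biomarker", "treatment", "classifier", "other"] },
              "elements": {
                "type": "array",
                "minItems": 1,
                "items": { "type": "string" },
                "uniqueItems": true
              },
              "control_element": { "type": ["string", "null"] }
            }
          }
        },
        "active_cells": {
          "description": "Each cell maps every axis name to one of its elements. Omitted: the full Cartesian product is active.",
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": { "type": "string" }
          }
        },
        "annotations": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["cell", "flags"],
            "properties": {
              "cell": { "type": "object", "additionalProperties": { "type": "string" } },
              "flags": {
                "type": "array",
                "items": { "enum": ["significant", "resistant", "combination"] }
              }
            }
          }
        },
        "cohorts": {
          "description": "Composite classifier element -> merged member labels (members must not appear as standalone elements).",
          "type": "object",
          "additionalProperties": { "type": "array", "items": { "type": "string" } }
        },
        "admissibility": {
          "description": "Treatment restrictions: a treatment listed here is allowed only with its listed classifiers.",
          "type": "array",
          "items": {
            "type": "object",
            "required": ["treatment", "classifier"],
            "properties": {
              "treatment": { "type": "string" },
              "classifier": { "type": "string" }
            }
          }
        }
      }
    },
    "history": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "axis", "payload"],
        "properties": {
          "kind": {
            "enum": ["add_element", "drop_element", "merge_into_cohort", "restrict_treatment", "add_treatment"]
          },
          "axis": { "type": "string" },
          "payload": { "type": "array" }
        }
      }
    }
  }
}
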
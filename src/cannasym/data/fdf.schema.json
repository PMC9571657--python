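{
  "$id": "https://example.org/cannasym/fdf-1.0.schema.json",
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Florescence Description Format (FDF) 1.0",
  "description": "One Canna partial florescence: branching topology with bract placements, observed per-flower floral diagrams, and provenance. Enforced structurally by cannasym.fixtures.read_collection; this document states the contract.",
  "type": "object",
  "required": ["version", "id", "species", "pf_class", "topology"],
  "properties": {
    "version": {"const": "1.0"},
    "id": {"type": "string"},
    "species": {"type": "string"},
    "pf_class": {
      "enum": ["single_flower", "cincinnus", "cyme_1f", "cyme_2f", "cyme_3f", "cyme_4f", "thyrse_2f", "thyrse_3f", "thyrse_4f"]
    },
    "normal": {"type": "boolean"},
    "figures": {"type": "array", "items": {"type": "string"}},
    "topology": {"$ref": "#/$defs/node"},
    "observed": {
      "type": "object",
      "additionalProperties": {"$ref": "#/$defs/phenotype"}
    },
    "annotations": {"type": "object"},
    "rule_exceptions": {"type": "object", "additionalProperties": {"type": "boolean"}}
  },
  "$defs": {
    "node": {
      "type": "object",
      "required": ["kind", "order"],
      "properties": {
        "kind": {"enum": ["axis", "flower"]},
        "order": {"type": "integer", "minimum": 0},
        "bract": {
          "oneOf": [
            {"type": "null"},
            {
              "type": "object",
              "required": ["order_index", "angle_deg"],
              "properties": {
                "order_index": {"type": "integer", "minimum": 1},
                "angle_deg": {"type": "number", "minimum": 0, "exclusiveMaximum": 360},
                "fused_with": {"type": ["string", "null"]}
              }
            }
          ]
        },
        "status": {"enum": ["mature", "aborted"]},
        "handedness": {"enum": ["sinistrorse", "dextrorse", null]},
        "children": {"type": "array", "items": {"$ref": "#/$defs/node"}}
      }
    },
    "phenotype": {
      "type": "object",
      "properties": {
        "sepal_count": {"type": ["integer", "null"], "minimum": 0},
        "petal_count": {"type": ["integer", "null"], "minimum": 0},
        "organ_states": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["whorl", "identity", "state", "position_deg"],
            "properties": {
              "whorl": {"enum": ["sepal", "petal", "outer_androecium", "inner_androecium", "gynoecium"]},
              "identity": {"enum": ["sepal", "petal", "outer_staminode", "inner_staminode", "labellum", "fertile_stamen", "stamen_appendage", "carpel"]},
              "state": {"enum": ["developed", "petaloid", "half_fertile", "fertile", "aborted"]},
              "position_deg": {"type": "number"}
            }
          }
        },
        "theca_count": {"enum": [0, 1, 2, null]},
        "appendage_side": {"enum": ["left", "right", "adaxial", "abaxial", "both", "none"]},
        "locule_count": {"type": ["integer", "null"], "minimum": 0},
        "style_form": {"enum": ["laminar", "filamentous", null]},
        "symmetry": {"enum": ["actinomorphic", "zygomorphic", "asymmetric", "intermediate", null]},
        "zygomorphy_axis": {"enum": ["dorsoventral", "mediolateral", null]}
      }
    }
  }
}
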
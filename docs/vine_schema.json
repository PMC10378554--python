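{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cvine-v1",
  "description": "Serialized C-vine structure; density grids of non-independent edges live in the companion numpy archive referenced by density_archive, indexed by grid_index.",
  "type": "object",
  "required": ["schema", "order", "d", "n_obs", "edges"],
  "properties": {
    "schema": {"const": "cvine-v1"},
    "order": {
      "type": "array",
      "items": {"type": "integer", "minimum": 0},
      "description": "root sequence: original variable indices sorted by descending sum of |Kendall tau|"
    },
    "d": {"type": "integer", "minimum": 2},
    "n_obs": {"type": "integer", "minimum": 1},
    "density_archive": {"type": "string"},
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["tree", "root", "partner", "conditioning",
                     "independent", "p_value", "kind", "grid_index"],
        "properties": {
          "tree": {"type": "integer", "minimum": 1},
          "root": {"type": "integer", "minimum": 0},
          "partner": {"type": "integer", "minimum": 0},
          "conditioning": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0},
            "description": "conditioning set: the first (tree-1) roots; the partner is conditioned on the root (C-vine convention)"
          },
          "independent": {"type": "boolean"},
          "p_value": {"type": "number", "minimum": 0, "maximum": 1},
          "kind": {
            "enum": ["flow", "histogram_fallback", "independence"]
          },
          "grid_index": {
            "type": ["integer", "null"],
            "description": "index into the density archive; null for independence edges"
          }
        }
      }
    }
  }
}
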
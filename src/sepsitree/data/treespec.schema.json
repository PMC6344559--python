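{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "sepsitree decision-tree risk model",
  "type": "object",
  "required": ["outcome_name", "baseline_rate", "nodes"],
  "properties": {
    "outcome_name": {"type": "string"},
    "baseline_rate": {"type": "number", "minimum": 0, "maximum": 1},
    "root": {"type": "string", "default": "1"},
    "nodes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "n", "n_event"],
        "properties": {
          "id": {"type": "string"},
          "n": {"type": "integer", "minimum": 1},
          "n_event": {"type": "integer", "minimum": 0},
          "event_rate": {"type": "number", "minimum": 0, "maximum": 1},
          "variable": {
            "enum": ["il8", "ccl3", "hspa1b", "gzmb", "mmp8", "age_years", "platelet_k_mcl"]
          },
          "threshold": {"type": "number"},
          "units": {"type": "string"},
          "children": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 2,
            "maxItems": 2
          },
          "risk_label": {"enum": ["low", "high"]}
        },
        "dependentRequired": {
          "variable": ["threshold", "children"],
          "children": ["variable"]
        }
      }
    }
  }
}
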
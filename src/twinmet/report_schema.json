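{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "twinmet cascade report",
  "type": "object",
  "required": ["provenance", "discovery", "selection", "replication",
               "validation_candidates", "validation", "sensitivity"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["config", "config_hash", "n_subjects", "n_features"],
      "properties": {
        "config": {"type": "object"},
        "config_hash": {"type": "string"},
        "n_subjects": {"type": "integer"},
        "n_features": {"type": "integer"},
        "exclusion_counts": {"type": "object"}
      }
    },
    "discovery": {
      "type": "object",
      "required": ["features", "ratios"],
      "properties": {
        "features": {"type": "array"},
        "ratios": {"type": "array"}
      }
    },
    "selection": {
      "type": "object",
      "required": ["features", "ratios"],
      "properties": {
        "features": {"type": "array"},
        "ratios": {"type": "array"}
      }
    },
    "replication": {
      "type": "object",
      "required": ["features", "ratios"],
      "properties": {
        "features": {"type": "array"},
        "ratios": {"type": "array"}
      }
    },
    "validation_candidates": {
      "type": "object",
      "required": ["features", "feature_book"],
      "properties": {
        "features": {"type": "array"},
        "feature_book": {"type": "array"},
        "ratio_book": {"type": "array"}
      }
    },
    "validation": {
      "type": "object",
      "required": ["features"],
      "properties": {
        "features": {"type": "array"},
        "ratio": {"type": "array"}
      }
    },
    "sensitivity": {
      "type": "object",
      "required": ["features"],
      "properties": {
        "features": {"type": "array"},
        "ratios": {"type": "array"}
      }
    }
  }
}
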
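{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "molbias experiment report",
  "type": "object",
  "required": ["config_hash", "target", "scenario", "methods", "per_trial_mae", "summary"],
  "properties": {
    "config_hash": {"type": "string"},
    "target": {"type": "string"},
    "scenario": {"type": "integer"},
    "methods": {"type": "array", "items": {"type": "string"}},
    "per_trial_mae": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "number"}}
    },
    "summary": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["mean", "std"],
        "properties": {
          "mean": {"type": "number"},
          "std": {"type": "number"},
          "t": {"type": "number"},
          "p": {"type": "number"},
          "stars": {"type": "string", "enum": ["", "*", "**"]}
        }
      }
    },
    "binned": {"type": "object"},
    "densities": {"type": "object"},
    "propensity_accuracy": {"type": "array", "items": {"type": "number"}}
  }
}
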
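{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ependysurv master report",
  "type": "object",
  "required": [
    "schema_version", "seed", "endpoint", "horizon_months", "n_samples",
    "n_labeled", "n_indeterminate", "filter_report", "chosen_hyperparams",
    "models"
  ],
  "properties": {
    "schema_version": {"const": 1},
    "seed": {"type": "integer"},
    "endpoint": {"enum": ["PFS", "OS"]},
    "horizon_months": {"type": "number", "exclusiveMinimum": 0},
    "n_samples": {"type": "integer", "minimum": 0},
    "n_labeled": {"type": "integer", "minimum": 0},
    "n_indeterminate": {"type": "integer", "minimum": 0},
    "filter_report": {
      "type": "object",
      "required": [
        "n_input_cpgs", "n_after_intersection", "n_blacklisted",
        "n_batch_removed", "n_final", "removed_ids", "notes"
      ]
    },
    "chosen_hyperparams": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["kernel", "C", "gamma"],
        "properties": {
          "kernel": {"enum": ["LINEAR", "RBF"]},
          "C": {"type": "number", "exclusiveMinimum": 0},
          "gamma": {"type": ["number", "null"]}
        }
      }
    },
    "models": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": [
          "model_tag", "n_scored", "n_rejected", "n_indeterminate",
          "confusion", "accuracy", "balanced_accuracy", "coverage",
          "logrank_chi2", "logrank_p", "reliability"
        ],
        "properties": {
          "confusion": {
            "type": "object",
            "required": ["tp", "fp", "fn", "tn"]
          },
          "accuracy": {"type": "number", "minimum": 0, "maximum": 1},
          "balanced_accuracy": {
            "type": ["number", "null"], "minimum": 0, "maximum": 1
          },
          "coverage": {"type": "number", "minimum": 0, "maximum": 1},
          "reliability": {"type": "array"}
        }
      }
    }
  }
}
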
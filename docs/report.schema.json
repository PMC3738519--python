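{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "twindow study report",
  "type": "object",
  "required": ["per_participant", "group", "provenance"],
  "properties": {
    "per_participant": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "id", "guess_rate", "race", "rt_twi", "posterior_medians",
          "toj_twi", "retained", "dissociation_soas", "malleable"
        ],
        "properties": {
          "id": {"type": "string"},
          "guess_rate": {"type": "number"},
          "race": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["soa", "p", "significant", "untestable", "borderline"],
              "properties": {
                "soa": {"type": "integer"},
                "d": {"type": ["number", "null"]},
                "p": {"type": "number", "minimum": 0, "maximum": 1},
                "significant": {"type": "boolean"},
                "untestable": {"type": "boolean"},
                "borderline": {"type": "boolean"}
              }
            }
          },
          "rt_twi": {
            "type": ["object", "null"],
            "required": ["lower", "upper", "members"],
            "properties": {
              "lower": {"type": "integer"},
              "upper": {"type": "integer"},
              "members": {"type": "array", "items": {"type": "integer"}}
            }
          },
          "posterior_medians": {
            "type": "object",
            "required": ["mu", "sigma", "lambda_a", "lambda_v"],
            "properties": {
              "mu": {"type": "number"},
              "sigma": {"type": "number"},
              "lambda_a": {"type": "number"},
              "lambda_v": {"type": "number"}
            }
          },
          "toj_twi": {
            "type": "object",
            "required": ["threshold_a", "threshold_v", "width"],
            "properties": {
              "threshold_a": {"type": "number"},
              "threshold_v": {"type": "number"},
              "width": {"type": "number"}
            }
          },
          "retained": {"type": "boolean"},
          "exclusion_reason": {"type": ["string", "null"]},
          "dissociation_soas": {"type": "array", "items": {"type": "integer"}},
          "malleable": {"type": "boolean"},
          "mean_toj_accuracy_at_dissociation": {"type": ["number", "null"]}
        }
      }
    },
    "group": {
      "type": "object",
      "required": ["illustrative", "sign_permutation_p", "rt_twi", "psychometric", "comparison", "n_retained"],
      "properties": {
        "illustrative": {"type": "boolean"},
        "sign_permutation_p": {"type": "object"},
        "rt_twi": {"type": ["object", "null"]},
        "psychometric": {"type": ["object", "null"]},
        "comparison": {"type": ["object", "null"]},
        "n_retained": {"type": "integer"}
      }
    },
    "provenance": {
      "type": "object",
      "required": [
        "package", "version", "seed", "n_iter", "alpha", "percentiles",
        "n_samples", "burn_in", "thin", "n_participants"
      ],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "n_iter": {"type": "integer"},
        "alpha": {"type": "number"},
        "percentiles": {"type": "array", "items": {"type": "number"}},
        "n_samples": {"type": "integer"},
        "burn_in": {"type": "integer"},
        "thin": {"type": "integer"},
        "n_participants": {"type": "integer"}
      }
    }
  }
}
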
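{
  "$defs": {
    "KMCurveModel": {
      "properties": {
        "survival_prob": {
          "items": {
            "type": "number"
          },
          "title": "Survival Prob",
          "type": "array"
        },
        "time": {
          "items": {
            "type": "number"
          },
          "title": "Time",
          "type": "array"
        }
      },
      "required": [
        "time",
        "survival_prob"
      ],
      "title": "KMCurveModel",
      "type": "object"
    }
  },
  "properties": {
    "curves": {
      "additionalProperties": {
        "$ref": "#/$defs/KMCurveModel"
      },
      "title": "Curves",
      "type": "object"
    },
    "logrank_chi2": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Logrank Chi2"
    },
    "logrank_p": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Logrank P"
    }
  },
  "required": [
    "curves",
    "logrank_chi2",
    "logrank_p"
  ],
  "title": "KMModel",
  "type": "object"
}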
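{
  "$defs": {
    "SelectionLevelModel": {
      "properties": {
        "best_subset": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "title": "Best Subset"
        },
        "k": {
          "title": "K",
          "type": "integer"
        },
        "loo_accuracy": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Loo Accuracy"
        },
        "n_subsets_evaluated": {
          "title": "N Subsets Evaluated",
          "type": "integer"
        }
      },
      "required": [
        "k",
        "best_subset",
        "loo_accuracy",
        "n_subsets_evaluated"
      ],
      "title": "SelectionLevelModel",
      "type": "object"
    }
  },
  "properties": {
    "levels": {
      "items": {
        "$ref": "#/$defs/SelectionLevelModel"
      },
      "title": "Levels",
      "type": "array"
    },
    "selected": {
      "items": {
        "type": "string"
      },
      "title": "Selected",
      "type": "array"
    },
    "selected_accuracy": {
      "title": "Selected Accuracy",
      "type": "number"
    },
    "stopped_at": {
      "title": "Stopped At",
      "type": "integer"
    }
  },
  "required": [
    "levels",
    "stopped_at",
    "selected",
    "selected_accuracy"
  ],
  "title": "SelectionTraceModel",
  "type": "object"
}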
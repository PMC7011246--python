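{
  "properties": {
    "dropped": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Dropped",
      "type": "array"
    },
    "kept": {
      "items": {
        "type": "string"
      },
      "title": "Kept",
      "type": "array"
    },
    "threshold": {
      "title": "Threshold",
      "type": "number"
    }
  },
  "required": [
    "kept",
    "dropped",
    "threshold"
  ],
  "title": "ReductionReportModel",
  "type": "object"
}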
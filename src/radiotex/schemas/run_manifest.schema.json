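{
  "properties": {
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "library_versions": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Library Versions",
      "type": "object"
    },
    "n_features": {
      "title": "N Features",
      "type": "integer"
    },
    "n_subjects": {
      "title": "N Subjects",
      "type": "integer"
    },
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "wall_clock_seconds": {
      "title": "Wall Clock Seconds",
      "type": "number"
    }
  },
  "required": [
    "config_hash",
    "seed",
    "n_subjects",
    "n_features",
    "library_versions",
    "wall_clock_seconds"
  ],
  "title": "RunManifestModel",
  "type": "object"
}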
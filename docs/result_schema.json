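{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "crforest detection results",
  "description": "Document written to arrays.json by write_results / `crf detect`. All coordinates are 1-based inclusive.",
  "type": "object",
  "required": ["coordinates", "arrays"],
  "properties": {
    "coordinates": {"const": "1-based inclusive"},
    "arrays": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["genome_id", "repeat_intervals", "spacer_intervals",
                     "repeat_seqs", "spacer_seqs", "consensus_repeat",
                     "label", "vote", "status"],
        "properties": {
          "genome_id": {"type": "string"},
          "repeat_intervals": {
            "type": "array",
            "items": {"type": "array", "prefixItems": [{"type": "integer"}, {"type": "integer"}]}
          },
          "spacer_intervals": {
            "type": "array",
            "items": {"type": "array", "prefixItems": [{"type": "integer"}, {"type": "integer"}]}
          },
          "repeat_seqs": {"type": "array", "items": {"type": "string"}},
          "spacer_seqs": {"type": "array", "items": {"type": "string"}},
          "consensus_repeat": {"type": "string"},
          "label": {"enum": ["repeat", "random"]},
          "vote": {"type": "number", "minimum": 0, "maximum": 1,
                   "description": "fraction of forest trees voting 'repeat'"},
          "status": {"enum": ["valid", "rejected"]},
          "rejection_stage": {
            "type": ["string", "null"],
            "description": "null for valid arrays; otherwise 'min_repeats', 'classifier', 'classifier:unfeaturizable', or 'filters:<failed rule names>'"
          },
          "filter_report": {
            "type": ["object", "null"],
            "properties": {
              "rules": {
                "type": "object",
                "additionalProperties": {
                  "type": "object",
                  "required": ["passed", "statistic"],
                  "properties": {
                    "passed": {"type": "boolean"},
                    "statistic": {"type": "number"},
                    "detail": {"type": "string"}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
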
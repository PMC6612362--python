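{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "opiconvert audit record (one JSON-lines entry)",
  "description": "One logged calculation. The schema is closed: additionalProperties is false so no free-text or patient-identifiable field can ever enter the log; indication is restricted to a fixed category list.",
  "type": "object",
  "required": [
    "record_id", "timestamp", "kind", "index_drug", "index_route", "index_dose",
    "target_drug", "target_route", "status", "ome", "exact_dose",
    "practical_dose", "warnings", "indication", "formulary_version"
  ],
  "additionalProperties": false,
  "properties": {
    "record_id": {"type": "integer", "minimum": 1},
    "timestamp": {"type": "string", "description": "ISO-8601 UTC"},
    "kind": {"enum": ["conversion", "breakthrough"]},
    "index_drug": {"type": "string"},
    "index_route": {"enum": ["oral", "subcutaneous", "transdermal"]},
    "index_dose": {"type": "string", "description": "decimal string"},
    "target_drug": {"type": ["string", "null"]},
    "target_route": {"enum": ["oral", "subcutaneous", "transdermal", null]},
    "status": {"enum": ["ok", "no_guideline_equivalence", "unsupported_drug"]},
    "ome": {"type": ["string", "null"], "description": "decimal string, mg/24h"},
    "exact_dose": {"type": ["string", "null"]},
    "practical_dose": {"type": ["string", "null"]},
    "warnings": {
      "type": "array",
      "items": {
        "enum": ["renal_caution", "below_smallest_patch", "above_largest_patch", "large_dose"]
      }
    },
    "indication": {
      "enum": ["cancer pain", "non-cancer pain", "end of life", "opioid toxicity", "renal impairment", "unspecified"]
    },
    "formulary_version": {"type": "string"}
  }
}
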
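{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "opiconvert CLI --json output",
  "type": "object",
  "required": ["status", "formulary_version", "warnings"],
  "additionalProperties": false,
  "properties": {
    "status": {"enum": ["ok", "no_guideline_equivalence", "unsupported_drug"]},
    "formulary_version": {"type": "string"},
    "ome_mg_per_24h": {"type": ["string", "null"]},
    "exact_target_dose": {"type": ["string", "null"]},
    "practical_target_dose": {"type": ["string", "null"]},
    "target_unit": {"type": ["string", "null"]},
    "warnings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "message"],
        "additionalProperties": false,
        "properties": {
          "code": {
            "enum": ["renal_caution", "below_smallest_patch", "above_largest_patch", "large_dose"]
          },
          "message": {"type": "string"}
        }
      }
    }
  }
}
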
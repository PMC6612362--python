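{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "opiconvert formulary file",
  "description": "Data-driven equianalgesic conversion formulary. All dose numbers are decimal; units are fixed by route (mg/24h for oral and subcutaneous, microgram/h for transdermal) and never appear inside numeric fields.",
  "type": "object",
  "required": ["version"],
  "additionalProperties": false,
  "properties": {
    "version": {"type": ["string", "number"]},
    "drugs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "route"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "route": {"enum": ["oral", "subcutaneous", "transdermal"]},
          "supported": {"type": "boolean", "default": true},
          "renal_risk": {"type": "boolean", "default": false}
        }
      }
    },
    "factors": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["drug", "route", "ome_per_unit"],
        "additionalProperties": false,
        "properties": {
          "drug": {"type": "string"},
          "route": {"enum": ["oral", "subcutaneous", "transdermal"]},
          "ome_per_unit": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "patch_tables": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["strength", "ome_low", "ome_high"],
          "additionalProperties": false,
          "properties": {
            "strength": {"type": "number", "exclusiveMinimum": 0},
            "ome_low": {"type": "number", "exclusiveMinimum": 0},
            "ome_high": {"type": "number", "exclusiveMinimum": 0}
          }
        }
      }
    },
    "defaults": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "breakthrough_divisor": {"type": "number", "exclusiveMinimum": 0},
        "egfr_warning_threshold": {"type": "number", "exclusiveMinimum": 0},
        "large_dose_ome_threshold": {"type": "number", "exclusiveMinimum": 0},
        "practical_increments": {
          "type": "object",
          "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    }
  }
}
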
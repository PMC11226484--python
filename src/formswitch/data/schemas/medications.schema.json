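{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Reconciled cohort medications table",
  "type": "object",
  "required": [
    "patient_id"
  ],
  "properties": {
    "patient_id": {
      "type": "string"
    },
    "product_name": {
      "type": "string"
    },
    "components": {
      "type": "string"
    },
    "dosage_form": {
      "type": "string"
    },
    "administration_times": {
      "type": "string"
    },
    "prescribed_during_stay": {
      "type": "string",
      "enum": [
        "true",
        "false"
      ]
    },
    "self_medication": {
      "type": "string",
      "enum": [
        "true",
        "false"
      ]
    },
    "provenance": {
      "type": "string"
    },
    "conflicts": {
      "type": "string"
    }
  }
}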
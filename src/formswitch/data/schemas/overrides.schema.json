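{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Pharmacist override entries (patient-individual switching)",
  "type": "object",
  "required": ["patient_id", "medication", "target_product"],
  "properties": {
    "patient_id": {"type": "string"},
    "medication": {"type": "string"},
    "target_product": {"type": "string"},
    "note": {"type": "string"}
  }
}
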
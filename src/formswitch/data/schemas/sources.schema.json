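{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Per-patient medication source records",
  "type": "object",
  "required": ["patient_id", "source"],
  "properties": {
    "patient_id": {"type": "string"},
    "source": {"type": "string", "enum": ["interview", "medication_list", "medical_documents"]},
    "product_name": {"type": "string"},
    "ingredients": {"type": "string"},
    "dosage_form": {"type": "string"},
    "administration_times": {"type": "string"},
    "prescribed_during_stay": {"type": "string", "enum": ["true", "false"]},
    "self_medication": {"type": "string", "enum": ["true", "false"]}
  }
}
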
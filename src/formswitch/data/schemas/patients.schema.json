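{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Cohort patients table",
  "type": "object",
  "required": ["patient_id", "age", "department"],
  "properties": {
    "patient_id": {"type": "string"},
    "age": {"type": "integer"},
    "department": {"type": "string"},
    "main_source": {"type": "string", "enum": ["interview", "medication_list", "medical_documents"]}
  }
}
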
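{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Substitution-exclusion list",
  "type": "object",
  "required": ["ingredient"],
  "properties": {
    "ingredient": {"type": "string"},
    "salt": {"type": "string"}
  }
}
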
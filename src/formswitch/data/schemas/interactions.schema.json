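{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Drug-drug interaction table",
  "type": "object",
  "required": ["ingredient_a", "ingredient_b", "severity"],
  "properties": {
    "ingredient_a": {"type": "string"},
    "ingredient_b": {"type": "string"},
    "severity": {"type": "string"}
  }
}
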
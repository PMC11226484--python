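{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Potentially-inappropriate-medication catalogs",
  "type": "object",
  "required": ["ingredient", "catalog", "category"],
  "properties": {
    "ingredient": {"type": "string"},
    "catalog": {"type": "string", "enum": ["priscus", "forta"]},
    "category": {"type": "string", "enum": ["listed", "A", "B", "C", "D"]}
  }
}
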
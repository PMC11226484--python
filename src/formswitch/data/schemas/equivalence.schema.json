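{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Dose-equivalence table",
  "type": "object",
  "required": ["table_id", "source_ingredient", "source_strength", "target_ingredient", "target_strength", "match_level"],
  "properties": {
    "table_id": {"type": "string"},
    "source_ingredient": {"type": "string"},
    "source_strength": {"type": "string", "pattern": "^[0-9]"},
    "target_ingredient": {"type": "string"},
    "target_strength": {"type": "string", "pattern": "^[0-9]"},
    "match_level": {"type": "integer", "enum": ["4", "5"]}
  }
}
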
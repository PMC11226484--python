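{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Hospital formulary table",
  "type": "object",
  "required": ["product_name", "dosage_form", "components"],
  "properties": {
    "product_name": {"type": "string"},
    "dosage_form": {"type": "string"},
    "atc": {"type": "string", "pattern": "^[A-Za-z]([0-9]{2}([A-Za-z]([A-Za-z]([0-9]{2})?)?)?)?$"},
    "components": {"type": "string", "pattern": "^[^:;]+(\\|[^:;]+)?:[0-9]"}
  }
}
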
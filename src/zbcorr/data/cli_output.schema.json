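{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "zbcorr CLI JSON output",
  "type": "object",
  "required": ["command", "result"],
  "properties": {
    "command": {"type": "string"},
    "result": {"type": "object"},
    "warnings": {"type": "array", "items": {"type": "string"}}
  },
  "additionalProperties": false
}
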
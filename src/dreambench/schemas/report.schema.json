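{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dream-bench report",
  "type": "object",
  "required": ["command", "results"],
  "properties": {
    "command": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "results": {"type": "object"}
  }
}
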
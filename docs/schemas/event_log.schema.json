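{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Event log row",
 "description": "One timestamped event of a construction-based matrix test session. On disk: CSV with these columns (header required, UTF-8, comma-separated, '.' decimal) or JSON-lines with one object per line.",
 "type": "object",
 "required": ["participant_id", "item_id", "t", "kind"],
 "properties": {
  "participant_id": {"type": "string"},
  "item_id": {"type": "string", "description": "Must resolve in the item bank."},
  "t": {"type": "number", "minimum": 0, "description": "Seconds since item onset; nondecreasing within an item; <= the item's time limit."},
  "kind": {"enum": ["click", "submit", "timeout"], "description": "Exactly one terminal event (submit or timeout) per item, and it is last."},
  "symbol_id": {"type": ["string", "null"], "pattern": "^[^:]+:.+$", "description": "'<group>:<k>'; present iff kind == 'click'. Repeated clicks on a symbol toggle its selection."}
 }
}
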
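{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Item bank",
 "description": "JSON list of matrix items. Each symbol group is tied to one rule; every solution symbol must belong to some rule's group. Items with a single rule load but are excluded from analysis.",
 "type": "array",
 "items": {
  "type": "object",
  "required": ["item_id", "position", "rules", "solution"],
  "properties": {
   "item_id": {"type": "string"},
   "position": {"type": "integer", "minimum": 1, "description": "1-based administration order; unique across the bank."},
   "time_limit": {"type": "number", "exclusiveMinimum": 0, "default": 90.0},
   "rules": {
    "type": "array",
    "minItems": 1,
    "items": {
     "type": "object",
     "required": ["rule_id", "symbol_group", "n_required_clicks"],
     "properties": {
      "rule_id": {"type": "string"},
      "symbol_group": {"type": "string", "description": "Distinct across the item's rules."},
      "n_required_clicks": {"type": "integer", "minimum": 1, "description": "Symbols of this group in the correct solution."}
     }
    }
   },
   "solution": {
    "type": "array",
    "items": {"type": "string", "pattern": "^[^:]+:.+$"},
    "description": "Symbol ids of the correct response; per rule exactly n_required_clicks of them."
   }
  }
 }
}
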
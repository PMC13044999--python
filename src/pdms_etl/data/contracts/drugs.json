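{
  "name": "drugs",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "ingredient", "type": "str", "required": true},
    {"name": "kind", "type": "str", "required": true},
    {"name": "amount", "type": "float", "required": false},
    {"name": "rate", "type": "float", "required": false},
    {"name": "unit", "type": "str", "required": true},
    {"name": "start_ts", "type": "datetime", "required": true},
    {"name": "end_ts", "type": "datetime", "required": false}
  ],
  "plausibility": [
    {"field": "kind", "allowed": ["bolus", "infusion"]},
    {"field": "unit", "allowed": ["mg", "U", "mg/h", "U/h"]},
    {"field": "rate", "min": 0, "max": 10000},
    {"field": "amount", "min": 0, "max": 10000}
  ],
  "cross_field": [
    {"name": "start<end", "op": "lt", "left": "start_ts", "right": "end_ts"},
    {"name": "infusion_has_rate", "op": "required_if", "left": "rate", "when": {"kind": "infusion"}},
    {"name": "infusion_has_end", "op": "required_if", "left": "end_ts", "when": {"kind": "infusion"}},
    {"name": "bolus_has_amount", "op": "required_if", "left": "amount", "when": {"kind": "bolus"}}
  ]
}
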
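{
  "name": "drug_windows",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "ingredient", "type": "str", "required": true},
    {"name": "unit", "type": "str", "required": true},
    {"name": "total", "type": "float", "required": true},
    {"name": "window_start_ts", "type": "datetime", "required": true},
    {"name": "window_end_ts", "type": "datetime", "required": true}
  ],
  "plausibility": [
    {"field": "unit", "allowed": ["mg", "U"]},
    {"field": "total", "min": 0, "max": 1000000}
  ],
  "cross_field": [
    {"name": "window_start<=window_end", "op": "le", "left": "window_start_ts", "right": "window_end_ts"}
  ]
}
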
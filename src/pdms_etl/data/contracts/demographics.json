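{
  "name": "demographics",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "admission_ts", "type": "datetime", "required": true},
    {"name": "discharge_ts", "type": "datetime", "required": false},
    {"name": "age_at_admission", "type": "int", "required": true},
    {"name": "sex", "type": "str", "required": true},
    {"name": "ward", "type": "str", "required": true}
  ],
  "plausibility": [
    {"field": "age_at_admission", "min": 0, "max": 120},
    {"field": "sex", "allowed": ["f", "m", "d"]}
  ],
  "cross_field": [
    {"name": "admission<=discharge", "op": "le", "left": "admission_ts", "right": "discharge_ts"}
  ]
}
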
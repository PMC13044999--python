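{
  "name": "therapy_episodes",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "device_type", "type": "str", "required": true},
    {"name": "start_ts", "type": "datetime", "required": true},
    {"name": "end_ts", "type": "datetime", "required": false},
    {"name": "end_inferred", "type": "bool", "required": true},
    {"name": "ongoing", "type": "bool", "required": true},
    {"name": "n_source_records", "type": "int", "required": true}
  ],
  "plausibility": [
    {"field": "device_type", "allowed": ["ECMO", "dialysis", "microaxial_pump", "IABP"]},
    {"field": "n_source_records", "min": 1, "max": 1000000}
  ],
  "cross_field": [
    {"name": "start<end", "op": "lt", "left": "start_ts", "right": "end_ts"}
  ]
}
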
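{
  "name": "or_times",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "or_start_ts", "type": "datetime", "required": true},
    {"name": "or_end_ts", "type": "datetime", "required": true}
  ],
  "plausibility": [],
  "cross_field": [
    {"name": "or_start<=or_end", "op": "le", "left": "or_start_ts", "right": "or_end_ts"}
  ]
}
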
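{
  "name": "observations",
  "fields": [
    {"name": "case_id", "type": "str", "required": true},
    {"name": "variable_id", "type": "str", "required": true},
    {"name": "value", "type": "float", "required": true},
    {"name": "unit", "type": "str", "required": false},
    {"name": "ts", "type": "datetime", "required": true},
    {"name": "context", "type": "str", "required": false}
  ],
  "plausibility": [
    {"field": "value", "min": 0, "max": 300, "when": {"variable_id": "VAR_HR"}},
    {"field": "value", "min": 0, "max": 250, "when": {"variable_id": "VAR_MAP"}},
    {"field": "value", "min": 0, "max": 100, "when": {"variable_id": "VAR_SPO2"}},
    {"field": "value", "min": 20, "max": 45, "when": {"variable_id": "VAR_TEMP"}},
    {"field": "value", "min": 0, "max": 50, "when": {"variable_id": "VAR_LACT"}},
    {"field": "value", "min": 0, "max": 800, "when": {"variable_id": "VAR_PO2"}}
  ],
  "cross_field": []
}
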
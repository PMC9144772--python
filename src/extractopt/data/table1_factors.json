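[
  {"name": "extraction_time", "unit": "min", "low": 60, "mid": 90, "high": 120},
  {"name": "extraction_temperature", "unit": "degC", "low": 40, "mid": 50, "high": 60},
  {"name": "liquid_solid_ratio", "unit": "mL/g", "low": 8, "mid": 10, "high": 12},
  {"name": "ethanol_concentration", "unit": "pct", "low": 55, "mid": 70, "high": 85}
]
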
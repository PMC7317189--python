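[
  {"lower_pa": 0.0,     "upper_pa": 1e-5,  "label": "<0.00001",            "f_air_spray": 0.01},
  {"lower_pa": 1e-5,    "upper_pa": 1e-4,  "label": "0.00001 to <0.0001",  "f_air_spray": 0.1},
  {"lower_pa": 1e-4,    "upper_pa": 1e-3,  "label": "0.0001 to <0.001",    "f_air_spray": 0.2},
  {"lower_pa": 1e-3,    "upper_pa": 1e-2,  "label": "0.001 to <0.01",      "f_air_spray": 0.5},
  {"lower_pa": 1e-2,    "upper_pa": "inf", "label": ">=0.01",              "f_air_spray": 1.0}
]
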
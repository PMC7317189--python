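{
  "version": 0,
  "mass_balance_mode": "decoupled",
  "rows": [
    {"method": "spray", "lower_pa": 0.0, "upper_pa": "inf", "band_label": "N/A", "f_air": 1.0, "f_soil": 1.0, "f_surface_water": 0.2, "f_waste": 0.0, "sperc_id": "ERC 8d"}
  ]
}
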
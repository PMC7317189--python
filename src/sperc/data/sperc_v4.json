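{
  "version": 4,
  "mass_balance_mode": "decoupled",
  "rows": [
    {"method": "spray", "lower_pa": 0.0,  "upper_pa": 1e-5,  "band_label": "<0.00001",           "f_air": 0.01, "f_soil": 1.0, "f_surface_water": 0.002, "f_waste": 0.0, "sperc_id": "8d.2.v4"},
    {"method": "spray", "lower_pa": 1e-5, "upper_pa": 1e-4,  "band_label": "0.00001 to <0.0001", "f_air": 0.1,  "f_soil": 1.0, "f_surface_water": 0.002, "f_waste": 0.0, "sperc_id": "8d.2.v4"},
    {"method": "spray", "lower_pa": 1e-4, "upper_pa": 1e-3,  "band_label": "0.0001 to <0.001",   "f_air": 0.2,  "f_soil": 1.0, "f_surface_water": 0.002, "f_waste": 0.0, "sperc_id": "8d.2.v4"},
    {"method": "spray", "lower_pa": 1e-3, "upper_pa": 1e-2,  "band_label": "0.001 to <0.01",     "f_air": 0.5,  "f_soil": 1.0, "f_surface_water": 0.002, "f_waste": 0.0, "sperc_id": "8d.2.v4"},
    {"method": "spray", "lower_pa": 1e-2, "upper_pa": "inf", "band_label": ">=0.01",             "f_air": 1.0,  "f_soil": 0.0, "f_surface_water": 0.002, "f_waste": 0.0, "sperc_id": "8d.2.v4"},
    {"method": "granular", "lower_pa": 0.0,  "upper_pa": 1e-2,  "band_label": "<0.01",  "f_air": 0.0, "f_soil": 1.0, "f_surface_water": 0.0, "f_waste": 0.0001, "sperc_id": "8d.1.v4"},
    {"method": "granular", "lower_pa": 1e-2, "upper_pa": "inf", "band_label": ">=0.01", "f_air": 0.0, "f_soil": 1.0, "f_surface_water": 0.0, "f_waste": 0.0001, "sperc_id": "8d.1.v4"}
  ]
}
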
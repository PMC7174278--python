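{
  "description": "Placebo granule formulation: GAB sorption parameters and dry-basis masses per material. Dry-basis moisture F_w is referenced to the adsorbing structural excipients (Avicel, Hypromellose, Ac-Di-Sol).",
  "components": [
    {"material_name": "Mannitol",          "mass": 213.0, "m_o": 0.00068, "c_gab": 1.73,  "k_w": 0.87},
    {"material_name": "Avicel PH-101",     "mass": 96.0,  "m_o": 0.040,   "c_gab": 17.4,  "k_w": 0.80},
    {"material_name": "Hypromellose 2910", "mass": 17.0,  "m_o": 0.018,   "c_gab": 18.9,  "k_w": 0.99},
    {"material_name": "Ac-Di-Sol",         "mass": 5.0,   "m_o": 0.095,   "c_gab": 13.4,  "k_w": 0.92}
  ],
  "adsorbing_subset": ["Avicel PH-101", "Hypromellose 2910", "Ac-Di-Sol"]
}
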
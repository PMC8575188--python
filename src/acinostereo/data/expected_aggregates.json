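{
  "description": "Published day-level aggregates that the reproduce-tables command recomputes from the bundled per-animal tables. Counts are alveoli per acinus, volumes in mm^3, densities in mm^-3, diameters in um.",
  "mean_count":      {"4": 48,   "10": 89,   "21": 233,  "60": 702},
  "mean_volume_mm3": {"4": 0.03, "10": 0.04, "21": 0.10, "60": 0.74},
  "mean_density":    {"4": 2166, "10": 2831, "21": 2723, "60": 1080},
  "alveolar_diameter_um": {"4": 98, "10": 86, "21": 84, "60": 116},
  "sidak_threshold": 0.00167,
  "scale_factor_total_alveoli": 5.04,
  "scale_factor_alveolar_volume": 1.81,
  "quintile_ratio_day60": 3.94
}
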
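{
  "description": "Published day-level reference quantities for postnatal rat acinar morphometry (days 4, 10, 21, 60). Used as inputs to the derived-metric layer and for cross-study scale-factor comparisons against whole-lung histology-based stereology.",
  "days": [4, 10, 21, 60],
  "cohort_profiles": {
    "4":  {"mean_volume_mm3": 0.03, "cv_volume": 1.26, "mean_alveoli": 48,  "n_acini": 125, "skew_direction": "right"},
    "10": {"mean_volume_mm3": 0.04, "cv_volume": 1.25, "mean_alveoli": 89,  "n_acini": 58,  "skew_direction": "right"},
    "21": {"mean_volume_mm3": 0.10, "cv_volume": 0.90, "mean_alveoli": 233, "n_acini": 42,  "skew_direction": "right"},
    "60": {"mean_volume_mm3": 0.74, "cv_volume": 0.49, "mean_alveoli": 702, "n_acini": 43,  "skew_direction": "symmetric"}
  },
  "ductal_fractions": {
    "note": "Fraction of acinar volume attributed to alveoli proper (the remainder is alveolar duct). Back-solved from the published per-day alveolar-volume quotients; not printed directly in the source study.",
    "4": 0.80, "10": 0.74, "21": 0.72, "60": 0.77
  },
  "alveolar_volume_um3": {
    "own":       {"4": 498000.0, "10": 334000.0, "21": 307000.0, "60": 812000.0},
    "histology": {"4": 591000.0, "10": 249000.0, "21": 134000.0, "60": 293000.0}
  },
  "total_alveoli_millions": {
    "own":       {"4": 0.64, "10": 1.23, "21": 2.65, "60": 3.01},
    "histology": {"4": 0.823, "10": 3.538, "21": 14.303, "60": 19.297}
  },
  "n_acini_per_lung": {"4": 18260, "10": 14359, "21": 11203, "60": 4277},
  "quintile_tail_means_ul": {
    "4":  {"low": 0.0035, "high": 0.095},
    "10": {"low": 0.0071, "high": 0.11},
    "21": {"low": 0.018,  "high": 0.26},
    "60": {"low": 0.33,   "high": 1.3}
  },
  "sidak": {"family_alpha": 0.01, "n_comparisons": 6},
  "voxel_size_um": 1.48
}
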
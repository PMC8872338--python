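{
  "group_sizes": {
    "three_four_monthly": 146,
    "six_monthly": 47,
    "twelve_monthly": 284,
    "no_imaging": 346
  },
  "horizon_years": 5.0,
  "hazards": {
    "three_four_monthly": 0.1597,
    "six_monthly": 0.1196,
    "twelve_monthly": 0.0862,
    "no_imaging": 0.1022
  },
  "test": {"sensitivity": 0.79, "specificity": 0.90},
  "clinical_detection_prob": 0.40,
  "attrition_rate": 0.44,
  "extra_investigation_mean": 5.0,
  "extra_investigation_dispersion": 0.6,
  "seed": 1234,
  "strategies": [
    {"name": "three_four_monthly", "visits_per_year": 4, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "six_monthly", "visits_per_year": 2, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "twelve_monthly", "visits_per_year": 1, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "no_imaging", "visits_per_year": 0, "horizon_years": 5.0, "reviews_per_year": 2}
  ]
}
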
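{
  "strategies": [
    {"name": "three_four_monthly", "visits_per_year": 4, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "six_monthly", "visits_per_year": 2, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "twelve_monthly", "visits_per_year": 1, "horizon_years": 5.0, "reviews_per_year": 2},
    {"name": "no_imaging", "visits_per_year": 0, "horizon_years": 5.0, "reviews_per_year": 2}
  ],
  "test": {"sensitivity": 0.79, "specificity": 0.90},
  "epi": {
    "cum_recurrence_prob_5y": {
      "three_four_monthly": 0.55,
      "six_monthly": 0.45,
      "twelve_monthly": 0.35,
      "no_imaging": 0.40
    },
    "clinical_detection_prob": 0.40,
    "clinical_fp_rate": 0.0
  },
  "costs": {
    "imaging_unit_cost": 1128.75,
    "confirmatory_workup_cost": 1500.0,
    "clinic_visit_cost": 90.0,
    "treatment_cost_stage_iv": 115072.0,
    "cpi_factor": 1.0,
    "discount_rate": 0.05
  },
  "outcome_metric": "correct_diagnosis",
  "metric_mode": "proportion",
  "discount_effects": false,
  "wtp": 50000.0
}
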
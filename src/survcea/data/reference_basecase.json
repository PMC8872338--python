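{
  "description": "Published base-case per-strategy mean discounted cost (2020 AUD) and effectiveness for the two outcome metrics of the melanoma surveillance analysis. Used as example inputs for incremental analysis and as regression anchors.",
  "comparator": "no_imaging",
  "wtp": 50000.0,
  "correct_diagnosis": {
    "no_imaging": {"cost": 51149.0, "effect": 0.8770},
    "twelve_monthly": {"cost": 52160.0, "effect": 0.9181},
    "six_monthly": {"cost": 77998.0, "effect": 0.8824},
    "three_four_monthly": {"cost": 88387.0, "effect": 0.8845}
  },
  "error_avoided": {
    "no_imaging": {"cost": 1513.0, "effect": 0.8832},
    "twelve_monthly": {"cost": 9084.0, "effect": 0.8503},
    "six_monthly": {"cost": 16268.0, "effect": 0.8386},
    "three_four_monthly": {"cost": 25304.0, "effect": 0.7999}
  }
}
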
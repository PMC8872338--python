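param_path,base,low,high,family,mean,se
test.sensitivity,0.79,0.70,0.86,beta,0.79,0.04
test.specificity,0.90,0.80,0.96,beta,0.90,0.03
epi.cum_recurrence_prob_5y.twelve_monthly,0.35,0.28,0.42,beta,0.35,0.035
epi.cum_recurrence_prob_5y.no_imaging,0.40,0.32,0.48,beta,0.40,0.04
epi.cum_recurrence_prob_5y.six_monthly,0.45,0.36,0.54,beta,0.45,0.045
epi.cum_recurrence_prob_5y.three_four_monthly,0.55,0.44,0.66,beta,0.55,0.055
epi.clinical_detection_prob,0.40,0.25,0.55,beta,0.40,0.07
costs.treatment_cost_stage_iv,115072,103565,126579,gamma,115072,11507
costs.confirmatory_workup_cost,1500,1000,2000,gamma,1500,250
costs.imaging_unit_cost,1128.75,1128.75,1128.75,gamma,1128.75,100
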
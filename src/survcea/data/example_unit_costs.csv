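item_label,mbs_or_drg_code,raw_cost,price_year
pet_low_dose_ct,61553,953.70,2020
adjunctive_ct,61505,175.05,2020
fnab,30094,75.05,2020
other_tests,,300.00,2020
clinic_visit,105,90.00,2020
treatment_stage_iv,,115072.00,2020
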
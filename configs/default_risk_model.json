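{
  "description": "Demonstration logistic risk model fitted on a synthetic training cohort drawn from configs/default.json (architecture seed 0); valid only with the weight panel that architecture generates. Sex coded female=0/male=1, APOE as E4/E2 allele counts (E3E3 reference), age centred at 73 years. Not a clinical instrument.",
  "intercept": -0.19332859696300678,
  "beta_prs": 1.9540624090271363,
  "beta_age": 0.04713089731877873,
  "beta_sex": 0.2357535745407383,
  "beta_apoe_e4": 1.7040139140288972,
  "beta_apoe_e2": 0.15822957876481225,
  "prs_norm_mean": 0.40473497894158933,
  "prs_norm_sd": 0.6621980645193741,
  "threshold": 0.6,
  "sex_coding": {
    "female": 0.0,
    "male": 1.0
  },
  "age_center": 73.0
}
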
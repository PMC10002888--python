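{
  "n_subjects": 120,
  "n_snps": 100,
  "allele_freq_range": [
    0.05,
    0.95
  ],
  "beta_sd": 0.05,
  "age_mean": 73.0,
  "age_sd": 6.8,
  "age_range": [
    55.0,
    95.0
  ],
  "male_fraction": 0.5567484662576687,
  "apoe_genotype_probs": {
    "E3E3": 0.57,
    "E3E4": 0.33,
    "E4E4": 0.07,
    "E2E4": 0.02,
    "E2E3": 0.008,
    "E2E2": 0.002
  },
  "cn_fraction": 0.3496932515337423,
  "gamma_e4": 0.8,
  "gamma_age": 0.02,
  "link_slope": 2.0,
  "high_risk_fraction": 0.6,
  "baseline_mean": {
    "CN": 0.0,
    "MCI": -5.5
  },
  "baseline_sd": {
    "CN": 2.7,
    "MCI": 3.9
  },
  "slope_per_month": {
    "CN:low": 0.0033333333333333335,
    "CN:high": -0.025,
    "MCI:low": -0.05333333333333334,
    "MCI:high": -0.13666666666666666
  },
  "subject_slope_sd": 0.01,
  "visit_noise_sd": 1.5,
  "call_missing_rate": 0.005,
  "missing_visit_prob": {
    "bl": 0.0,
    "m06": 0.03,
    "m12": 0.05,
    "m24": 0.1,
    "m36": 0.25,
    "m48": 0.28,
    "m60": 0.5
  },
  "missing_component_prob": 0.02,
  "qc_violation_rates": {
    "missingness": 0.02,
    "maf": 0.02,
    "hwe": 0.02
  },
  "panel_flip_fraction": 0.5,
  "seed": 0
}
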
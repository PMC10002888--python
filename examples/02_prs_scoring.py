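"""Polygenic risk scoring with covariates on a synthetic cohort.

Simulates a small cohort, QCs the genotypes, fits a demonstration logistic
risk model on an independent training cohort sharing the same SNP panel,
and scores every subject: raw weighted dosage sum, normalized PRS,
predicted risk, and the high/low call at the 0.6 threshold.
"""

from dataclasses import asdict

from polyrisk_cog import SimulationConfig, apply_qc, score_cohort, simulate_cohort
from polyrisk_cog.pipeline import train_risk_model

config = SimulationConfig(**{**asdict(SimulationConfig()),
                             "n_subjects": 200, "n_snps": 150, "seed": 42})
model = train_risk_model(config, train_seed=1042)
cohort = simulate_cohort(config, subject_seed=2042)

qcd, _ = apply_qc(cohort.genotypes)
scores = score_cohort(qcd, cohort.panel, cohort.covariates, model)

print(scores.head(8).to_string(index=False, float_format=lambda x: f"{x:.4f}"))
high = (scores["risk_class"] == "high").mean()
print(f"\n{high:.1%} of subjects called high risk (predicted risk >= 0.6).")
print("raw_sum is sum_i dosage_i * beta_i over panel SNPs (missing calls "
      "imputed as 2 x effect-allele frequency); normalized_prs is its "
      "z-scored value; predicted_risk adds age, sex and APOE through the "
      "logistic model.")
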
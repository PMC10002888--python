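"""Risk-stratified longitudinal decline: the full analysis chain.

Runs the end-to-end pipeline on the default synthetic study conditions
(600 subjects, 500 SNPs, APOE E3E3/E3E4 analysis set) and prints the risk
timecourse table, the per-visit Welch comparisons, and the decliner
ROC/AUC with its DeLong confidence interval.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from polyrisk_cog import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    manifest = run_pipeline(tmp, seed=1)
    tc = pd.read_csv(Path(tmp) / "timecourse_risk.tsv", sep="\t")
    comparisons = pd.read_csv(Path(tmp) / "comparisons.tsv", sep="\t")
    roc = json.loads((Path(tmp) / "roc.json").read_text())

print("mean composite change from baseline by risk stratum:")
print(tc.pivot(index="visit", columns="stratum", values="mean_change")
        .round(2).to_string())
print("\nWelch high-vs-low comparisons per visit:")
print(comparisons[["visit", "n_a", "n_b", "mean_a", "mean_b", "t", "p"]]
      .round(4).to_string(index=False))
print(f"\ndecliner AUC {roc['auc']:.3f} "
      f"(DeLong 95% CI {roc['ci_low']:.3f}-{roc['ci_high']:.3f}), "
      f"{roc['n_cases']} decliners / {roc['n_controls']} stable.")
print("High-risk subjects (predicted risk >= 0.6) decline faster at every "
      "visit; the AUC measures how well predicted risk ranks subjects who "
      "lose >= 1 composite point within 5 years.")
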
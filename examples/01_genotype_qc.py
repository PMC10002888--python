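"""Variant quality control on a small genotype panel.

Builds a six-variant dosage matrix with one planted violation of each QC
filter (call missingness > 0.02, minor allele frequency < 0.01, exact
Hardy-Weinberg p < 1e-6), runs the filter chain, and prints the
per-variant report.
"""

import numpy as np

from polyrisk_cog import GenotypeMatrix, VariantRecord, apply_qc


def column(n0, n1, n2, missing=0):
    return [0.0] * n0 + [1.0] * n1 + [2.0] * n2 + [np.nan] * missing


columns = {
    "rs_clean_common": column(20, 20, 10),      # MAF 0.40, near HWE
    "rs_clean_quarter": column(30, 15, 5),      # MAF 0.25
    "rs_boundary_miss": column(25, 19, 5, 1),   # missingness exactly 0.02: passes
    "rs_high_missing": column(24, 19, 5, 2),    # missingness 0.04: fails
    "rs_monomorphic": column(50, 0, 0),         # MAF 0: fails
    "rs_all_het": column(0, 50, 0),             # heterozygote excess: fails HWE
}
matrix = GenotypeMatrix(
    subjects=[f"S{i}" for i in range(50)],
    variants=[VariantRecord(v, "1", k + 1, "A", "G") for k, v in enumerate(columns)],
    dosage=np.array(list(columns.values())).T,
)

filtered, report = apply_qc(matrix)
print(report.table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(f"\nretained {report.n_after} of {report.n_before} variants:",
      ", ".join(filtered.variant_ids))
print("A variant is kept iff missingness <= 0.02 AND MAF >= 0.01 AND "
      "exact-HWE p >= 1e-6; equality always passes.")
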
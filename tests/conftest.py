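"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive each quantity from its definition
(exact rational enumeration for the Hardy-Weinberg test, per-pair counting
for the AUC, the textbook Welch formulas, a direct per-subject loop for
the PRS) so the implementation under test is checked against a second,
independent route.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from polyrisk_cog.genotype_io import GenotypeMatrix, VariantRecord


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-rational enumeration oracle for the two-sided HWE exact test:
    P(h) = n_a! n_b! n! 2^h / ((2n)! aa! h! bb!), summed over all feasible
    heterozygote counts whose probability <= that of the observed count."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return Fraction(1)
    f = math.factorial

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = n - aa - h
        return Fraction(f(n_a) * f(n_b) * f(n) * 2**h, f(2 * n) * f(aa) * f(h) * f(bb))

    feasible = range(n_a % 2, min(n_a, n_b) + 1, 2)
    probs = {h: prob(h) for h in feasible}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


def auc_oracle(scores, labels) -> float:
    """AUC as the fraction of (case, control) pairs with case score higher,
    counting ties one half — counted pair by pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    cases = scores[labels]
    controls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Textbook Welch statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def prs_oracle(matrix: GenotypeMatrix, panel, subject: str) -> float:
    """Direct per-subject evaluation of the weighted score: for each panel
    SNP present in the matrix with compatible non-ambiguous alleles, add
    beta times the effect-allele dosage (missing -> 2 * eaf)."""
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    i = matrix.subjects.index(subject)
    by_id = {v.variant_id: (j, v) for j, v in enumerate(matrix.variants)}
    total = 0.0
    for e in panel:
        if complement.get(e.effect_allele) == e.other_allele:
            continue  # strand-ambiguous
        hit = by_id.get(e.variant_id)
        if hit is None:
            continue
        j, v = hit
        if {e.effect_allele, e.other_allele} != {v.allele_a, v.allele_b}:
            continue
        d = matrix.dosage[i, j]
        if np.isnan(d):
            d_eff = 2.0 * e.effect_allele_freq
        elif e.effect_allele == v.allele_b:
            d_eff = d
        else:
            d_eff = 2.0 - d
        total += d_eff * e.beta
    return total


# ---------------------------------------------------------------------------
# Fixture builders
# ---------------------------------------------------------------------------

def make_matrix(columns: dict[str, list], alleles: dict[str, tuple[str, str]] | None = None) -> GenotypeMatrix:
    """Build a matrix from {variant_id: dosage list}; None entries are
    missing calls. Default alleles A (ref) / C (effect)."""
    n = len(next(iter(columns.values())))
    subjects = [f"P{i + 1}" for i in range(n)]
    variants = []
    cols = []
    for k, (vid, dos) in enumerate(columns.items()):
        a, b = (alleles or {}).get(vid, ("A", "C"))
        variants.append(VariantRecord(vid, "1", k + 1, a, b))
        cols.append([np.nan if d is None else float(d) for d in dos])
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=np.array(cols).T)


@pytest.fixture
def qc_fixture_matrix() -> tuple[GenotypeMatrix, dict[str, str]]:
    """Six variants over 50 subjects: three clean, one planted violation of
    each QC filter. Returns (matrix, {variant_id: planted_failure})."""
    n = 50

    def geno(n0, n1, n2, missing=0):
        return [0] * n0 + [1] * n1 + [2] * n2 + [None] * missing

    columns = {
        "clean_common": geno(20, 20, 10),          # maf 0.4, mild het deficit
        "clean_quarter": geno(30, 15, 5),          # maf 0.25
        "clean_boundary_miss": geno(25, 19, 5, 1), # missingness exactly 0.02
        "fail_missing": geno(24, 19, 5, 2),        # missingness 0.04 > 0.02
        "fail_rare": geno(50, 0, 0),               # monomorphic, maf 0 < 0.01
        "fail_hwe": geno(0, 50, 0),                # all heterozygous
    }
    truth = {
        "fail_missing": "missingness",
        "fail_rare": "maf",
        "fail_hwe": "hwe",
    }
    return make_matrix(columns), truth
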
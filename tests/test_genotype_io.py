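"""Genotype parsing, per-variant statistics, and QC filtering."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyrisk_cog.genotype_io import (
    GenotypeParseError,
    QCThresholds,
    apply_qc,
    hwe_chisq_p,
    hwe_exact_p,
    read_dosage_table,
    read_genotypes,
    variant_maf,
    variant_missingness,
    write_dosage_table,
    write_vcf,
)

from conftest import hwe_oracle, make_matrix


VCF_BODY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0|1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t./1
1\t300\trs3\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
1\t400\trs4\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2
"""


class TestReaders:
    def test_vcf_dosage_and_missing_conventions(self, tmp_path):
        """ALT-dosage coding, phased==unphased, half-call and ./. missing,
        multi-allelic sites skipped with a warning."""
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_BODY)
        with pytest.warns(UserWarning, match="multi-allelic"):
            m = read_genotypes(p, "vcf")
        assert m.subjects == ["S1", "S2", "S3"]
        assert m.variant_ids == ["rs1", "rs2", "rs3"]  # rs4 skipped
        np.testing.assert_array_equal(m.dosage[:, 0], [1, 1, 2])
        assert np.isnan(m.dosage[0, 1]) and np.isnan(m.dosage[2, 1])
        assert m.dosage[1, 1] == 0
        assert (m.variants[0].allele_a, m.variants[0].allele_b) == ("A", "G")

    def test_vcf_duplicate_id_rejected(self, tmp_path):
        body = VCF_BODY.replace("rs2", "rs1")
        p = tmp_path / "dup.vcf"
        p.write_text(body)
        with pytest.raises(GenotypeParseError, match="duplicate"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            read_genotypes(p, "vcf")

    def test_dosage_table_round_trip(self, tmp_path):
        m = make_matrix({"rs1": [0, 1, 2, None], "rs2": [2, 2, 0, 1]})
        path = write_dosage_table(m, tmp_path / "d.tsv")
        back = read_dosage_table(path)
        assert back.subjects == m.subjects
        assert back.variant_ids == m.variant_ids
        np.testing.assert_array_equal(back.dosage, m.dosage)

    def test_dosage_table_rejects_invalid_cell(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("subject_id\trs1\nP1\t3\n")
        with pytest.raises(GenotypeParseError, match="invalid dosage"):
            read_dosage_table(p)

    def test_vcf_write_read_round_trip(self, tmp_path):
        m = make_matrix(
            {"rs1": [0, 1, 2], "rs2": [None, 1, 0]},
            alleles={"rs1": ("A", "G"), "rs2": ("T", "C")},
        )
        back = read_genotypes(write_vcf(m, tmp_path / "m.vcf"), "vcf")
        assert back.variant_ids == m.variant_ids
        assert [(v.allele_a, v.allele_b) for v in back.variants] == [
            ("A", "G"), ("T", "C")
        ]
        np.testing.assert_array_equal(back.dosage, m.dosage)

    def test_plink_text_pair(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "t.ped").write_text(
            "F1 P1 0 0 1 0 A A A G\n"
            "F2 P2 0 0 2 0 A G 0 0\n"
            "F3 P3 0 0 1 0 G G G G\n"
        )
        m = read_genotypes(tmp_path / "t.ped", "plink_text")
        assert m.subjects == ["P1", "P2", "P3"]
        # rs1: G is minor (3 of 6 alleles? A:3, G:3 -> tie broken to A major)
        v = m.variants[0]
        assert {v.allele_a, v.allele_b} == {"A", "G"}
        minor = v.allele_b
        expect = {"A": [2, 1, 0], "G": [0, 1, 2]}[minor]
        np.testing.assert_array_equal(m.dosage[:, 0], expect)
        assert np.isnan(m.dosage[1, 1])  # 0 0 -> missing


class TestVariantStats:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 1, 2, 2, 0, 1, 2, 1, 0, 2], 0.0), ([None] + [0] * 49, 0.02),
         ([None, None], 1.0)],
    )
    def test_missingness(self, dosages, expected):
        m = make_matrix({"v": dosages})
        assert variant_missingness(m, 0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 1, 2, 2], 0.375), ([0, 0, 0, 0], 0.0), ([2, 2, 2, 1, None], 0.125)],
    )
    def test_maf(self, dosages, expected):
        m = make_matrix({"v": dosages})
        assert variant_maf(m, 0) == pytest.approx(expected, abs=1e-15)

    def test_maf_all_missing_raises(self):
        m = make_matrix({"v": [None, None, None]})
        with pytest.raises(ValueError, match="all-missing"):
            variant_maf(m, 0)


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    @pytest.mark.parametrize("counts", [(3, 5, 2), (0, 50, 0), (10, 1, 10), (57, 14, 50)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(float(hwe_oracle(*counts)), abs=1e-15)

    def test_all_het_extreme_tail(self):
        """Complete heterozygote excess (0, 50, 0) sits deep in the tail:
        smaller p than every configuration with 50/50 alleles except the
        even-more-improbable complete homozygote split (25, 0, 25)."""
        p_allhet = hwe_exact_p(0, 50, 0)
        assert p_allhet == pytest.approx(float(hwe_oracle(0, 50, 0)), abs=1e-15)
        assert p_allhet < 1e-6
        for h in range(2, 49, 2):
            assert p_allhet < hwe_exact_p((50 - h) // 2, h, (50 - h) // 2)
        assert hwe_exact_p(25, 0, 25) < p_allhet

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @given(
        n_aa=st.integers(0, 25), n_ab=st.integers(0, 25), n_bb=st.integers(0, 25)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_properties(self, n_aa, n_ab, n_bb):
        """p in (0,1]; symmetric under allele-label swap; conditional
        probabilities sum to one."""
        if n_aa + n_ab + n_bb == 0:
            return
        p = hwe_exact_p(n_aa, n_ab, n_bb)
        assert 0.0 < p <= 1.0
        assert p == hwe_exact_p(n_bb, n_ab, n_aa)
        n_a, n_b = 2 * n_aa + n_ab, 2 * n_bb + n_ab
        if n_a and n_b:
            total = sum(
                _cond_prob(n_a, n_b, h)
                for h in range(n_a % 2, min(n_a, n_b) + 1, 2)
            )
            assert abs(float(total) - 1.0) < 1e-12

    def test_chisq_option_agrees_qualitatively(self):
        """The chi-square alternative reaches the same accept/reject
        conclusion as the exact test at moderate counts."""
        assert hwe_chisq_p(30, 50, 20) > 0.5 and hwe_exact_p(30, 50, 20) > 0.5
        assert hwe_chisq_p(5, 90, 5) < 1e-6 and hwe_exact_p(5, 90, 5) < 1e-6


def _cond_prob(n_a, n_b, h):
    from fractions import Fraction

    n = (n_a + n_b) // 2
    aa = (n_a - h) // 2
    bb = n - aa - h
    return Fraction(
        math.factorial(n_a) * math.factorial(n_b) * math.factorial(n) * 2**h,
        math.factorial(2 * n) * math.factorial(aa) * math.factorial(h) * math.factorial(bb),
    )


class TestApplyQC:
    def test_planted_fixture(self, qc_fixture_matrix):
        m, truth = qc_fixture_matrix
        filtered, report = apply_qc(m)
        assert set(report.failed_ids) == set(truth)
        assert filtered.n_variants == 3
        for vid, why in truth.items():
            row = report.table.set_index("variant_id").loc[vid]
            assert row[f"fail_{why}"], f"{vid} should fail {why}"
        # boundary: missingness exactly 0.02 passes
        assert "clean_boundary_miss" in report.retained_ids

    def test_identity_thresholds_retain_all(self, qc_fixture_matrix):
        m, _ = qc_fixture_matrix
        filtered, report = apply_qc(m, QCThresholds(1.0, 0.0, 0.0))
        assert filtered.n_variants == m.n_variants
        assert report.n_after == report.n_before

    def test_double_failure_counted_once_flagged_twice(self):
        # monomorphic AND 10% missing: fails missingness and maf
        m = make_matrix(
            {"bad": [0] * 45 + [None] * 5, "good": [0, 1, 2, 1, 0] * 10}
        )
        filtered, report = apply_qc(m)
        row = report.table.set_index("variant_id").loc["bad"]
        assert row["fail_missingness"] and row["fail_maf"]
        assert report.n_before - report.n_after == 1
        assert filtered.variant_ids == ["good"]

    def test_idempotent(self, qc_fixture_matrix):
        m, _ = qc_fixture_matrix
        once, _ = apply_qc(m)
        twice, rep2 = apply_qc(once)
        assert twice.variant_ids == once.variant_ids
        assert rep2.n_before == rep2.n_after

    def test_report_write(self, qc_fixture_matrix, tmp_path):
        import json

        m, _ = qc_fixture_matrix
        _, report = apply_qc(m)
        tsv, js = report.write(tmp_path / "run")
        assert tsv.exists() and js.exists()
        summary = json.loads(js.read_text())
        assert summary["n_before"] == 6 and summary["n_after"] == 3
        assert summary["filter_order"] == ["missingness", "maf", "hwe"]

    def test_empty_matrix_rejected(self):
        m = make_matrix({"v": [0, 1]})
        with pytest.raises(ValueError):
            apply_qc(m.subset_variants([]))
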
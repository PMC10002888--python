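"""Weight-panel handling, allele harmonization, scoring and risk model."""

import math

import numpy as np
import pytest

from polyrisk_cog.genotype_io import GenotypeMatrix, VariantRecord
from polyrisk_cog.prs import (
    CovariateRecord,
    RiskModel,
    WeightPanelEntry,
    align_panel,
    classify_risk,
    cohort_norm_constants,
    impute_missing_dosage,
    load_weight_panel,
    normalize_prs,
    predicted_risk,
    raw_prs,
    score_cohort,
    write_weight_panel,
)

from conftest import make_matrix, prs_oracle


PANEL_HEADER = "variant_id\teffect_allele\tother_allele\tbeta\teaf\n"


class TestWeightPanel:
    def test_well_formed_panel(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            PANEL_HEADER
            + "rs1\tC\tA\t0.12\t0.3\nrs2\tG\tT\t-0.05\t0.45\nrs3\tC\tT\t0.2\t0.9\n"
        )
        entries = load_weight_panel(p)
        assert len(entries) == 3
        assert entries[0].beta == 0.12

    @pytest.mark.parametrize(
        "body, match",
        [
            ("rs1\tC\tA\t0.1\t0.3\nrs1\tG\tT\t0.2\t0.4\n", "duplicate"),
            ("rs1\tC\tA\tnot_a_number\t0.3\n", ":2"),
            ("rs1\tC\tA\t0.1\t0.0\n", "outside"),
            ("rs1\tC\tA\t0.1\t1.0\n", "outside"),
        ],
    )
    def test_invalid_panels_rejected(self, tmp_path, body, match):
        p = tmp_path / "panel.tsv"
        p.write_text(PANEL_HEADER + body)
        with pytest.raises(ValueError, match=match):
            load_weight_panel(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text("variant_id\teffect_allele\tbeta\teaf\nrs1\tC\t0.1\t0.3\n")
        with pytest.raises(ValueError, match="missing panel columns"):
            load_weight_panel(p)

    def test_write_read_round_trip(self, tmp_path):
        entries = [
            WeightPanelEntry("rs1", "C", "A", 0.123456789012345, 0.3),
            WeightPanelEntry("rs2", "T", "G", -1e-7, 0.987654321),
        ]
        assert load_weight_panel(write_weight_panel(entries, tmp_path / "p.tsv")) == entries


class TestAlignment:
    def _matrix(self):
        return make_matrix(
            {"rs1": [0, 1, 2], "rs2": [2, 1, 0], "rs3": [0, 0, 1], "rs4": [1, 1, 1]},
            alleles={
                "rs1": ("A", "C"),
                "rs2": ("T", "G"),
                "rs3": ("A", "T"),  # strand-ambiguous
                "rs4": ("A", "G"),
            },
        )

    def test_orientation_flip_and_drops(self):
        m = self._matrix()
        panel = [
            WeightPanelEntry("rs1", "C", "A", 0.1, 0.3),  # as-is
            WeightPanelEntry("rs2", "T", "G", 0.2, 0.4),  # flipped
            WeightPanelEntry("rs3", "A", "T", 0.3, 0.5),  # ambiguous -> dropped
            WeightPanelEntry("rs4", "T", "C", 0.4, 0.6),  # allele mismatch
            WeightPanelEntry("rs9", "C", "A", 0.5, 0.7),  # absent
        ]
        aligned = align_panel(m, panel)
        assert aligned.report() == {
            "n_used": 2, "n_flipped": 1, "n_ambiguous": 1, "n_absent": 1,
            "n_mismatched": 1,
        }
        d = aligned.aligned_dosage(m)
        np.testing.assert_array_equal(d[:, 0], [0, 1, 2])  # unchanged
        np.testing.assert_array_equal(d[:, 1], [0, 1, 2])  # 2 - d

    def test_zero_overlap_is_error(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="no panel SNPs overlap"):
            align_panel(m, [WeightPanelEntry("rsX", "C", "A", 0.1, 0.5)])


class TestScoring:
    def test_imputation_expected_dosage(self):
        assert impute_missing_dosage(WeightPanelEntry("r", "C", "A", 0.1, 0.25)) == 0.5
        assert impute_missing_dosage(WeightPanelEntry("r", "C", "A", 0.1, 0.5)) == 1.0

    def test_raw_prs_arithmetic(self):
        assert raw_prs(
            np.array([[0.0, 1.0, 2.0]]), np.array([0.1, -0.2, 0.3]), np.zeros(3)
        )[0] == pytest.approx(0.4)
        assert raw_prs(np.array([[1.0, 2.0]]), np.zeros(2), np.zeros(2))[0] == 0.0

    def test_all_missing_subject_equals_closed_form(self):
        entries = [
            WeightPanelEntry(f"rs{i}", "C", "A", b, f)
            for i, (b, f) in enumerate([(0.1, 0.2), (-0.3, 0.7), (0.05, 0.5)])
        ]
        d = np.full((1, 3), np.nan)
        raw = raw_prs(d, np.array([e.beta for e in entries]),
                      np.array([impute_missing_dosage(e) for e in entries]))
        expected = sum(2 * e.effect_allele_freq * e.beta for e in entries)
        assert raw[0] == pytest.approx(expected, abs=1e-15)

    def test_normalization(self):
        model = RiskModel(prs_norm_mean=2.0, prs_norm_sd=0.5)
        assert normalize_prs(2.0, model) == 0.0
        assert normalize_prs(2.5, model) == 1.0

    def test_cohort_standardization_gives_unit_moments(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(3.0, 1.7, size=200)
        mean, sd = cohort_norm_constants(raw)
        z = (raw - mean) / sd
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=1) - 1.0) < 1e-9


class TestRiskModel:
    COV = CovariateRecord("s", 70.0, "female", "E3E3")

    def test_logistic_closed_forms(self):
        assert predicted_risk(0.0, self.COV, RiskModel(beta_prs=0.0)) == 0.5
        m = RiskModel(intercept=math.log(3.0), beta_prs=0.0)
        assert predicted_risk(5.0, self.COV, m) == pytest.approx(0.75)

    def test_apoe_e4_monotone(self):
        m = RiskModel(beta_apoe_e4=0.5)
        e33 = predicted_risk(0.0, CovariateRecord("s", 70, "female", "E3E3"), m)
        e34 = predicted_risk(0.0, CovariateRecord("s", 70, "female", "E3E4"), m)
        e44 = predicted_risk(0.0, CovariateRecord("s", 70, "female", "E4E4"), m)
        assert e33 < e34 < e44

    def test_monotone_in_prs_when_beta_positive(self):
        m = RiskModel(beta_prs=0.8)
        risks = [predicted_risk(z, self.COV, m) for z in np.linspace(-3, 3, 13)]
        assert all(a < b for a, b in zip(risks, risks[1:]))
        assert all(0.0 < r < 1.0 for r in risks)

    def test_zero_prs_weight_ignores_genotype(self):
        m = RiskModel(beta_prs=0.0, beta_age=0.1, beta_sex=0.3)
        cov = CovariateRecord("s", 72.0, "male", "E3E4")
        assert predicted_risk(-5.0, cov, m) == predicted_risk(+5.0, cov, m)

    @pytest.mark.parametrize(
        "p, threshold, expected",
        [(0.60, 0.6, "high"), (0.599, 0.6, "low"), (0.001, 0.0, "high")],
    )
    def test_classification_boundary(self, p, threshold, expected):
        assert classify_risk(p, threshold) == expected

    def test_json_round_trip(self, tmp_path):
        m = RiskModel(intercept=-1.2, beta_prs=1.5, beta_age=0.04, threshold=0.6)
        m.to_json(tmp_path / "m.json", description="test")
        assert RiskModel.from_json(tmp_path / "m.json") == m

    def test_invalid_covariates_rejected(self):
        with pytest.raises(ValueError):
            CovariateRecord("s", -1.0, "female", "E3E3")
        with pytest.raises(ValueError):
            CovariateRecord("s", 70.0, "female", "E5E5")


def _random_instance(rng, n_subjects=6, n_snps=50):
    """Random matrix/panel pair with flips, ambiguous SNPs, mismatches and
    missing calls."""
    pairs = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("A", "T")]
    variants, cols, panel = [], [], []
    for j in range(n_snps):
        a, b = pairs[rng.integers(0, len(pairs))]
        vid = f"rs{j}"
        variants.append(VariantRecord(vid, "1", j + 1, a, b))
        col = rng.integers(0, 3, size=n_subjects).astype(float)
        col[rng.random(n_subjects) < 0.15] = np.nan
        cols.append(col)
        beta = rng.normal(0, 0.3)
        freq = rng.uniform(0.05, 0.95)
        orient = rng.random()
        if orient < 0.4:
            panel.append(WeightPanelEntry(vid, b, a, beta, freq))
        elif orient < 0.8:
            panel.append(WeightPanelEntry(vid, a, b, -beta, 1 - freq))
        else:  # allele mismatch: panel on different alleles
            panel.append(WeightPanelEntry(vid, "C" if a != "C" and b != "C" else "G",
                                          "T" if a != "T" and b != "T" else "A",
                                          beta, freq))
    m = GenotypeMatrix(
        subjects=[f"S{i}" for i in range(n_subjects)],
        variants=variants,
        dosage=np.column_stack(cols),
    )
    return m, panel


class TestEndToEndOracle:
    def test_matches_brute_force_scorer(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m, panel = _random_instance(rng)
            aligned = align_panel(m, panel)
            raw = raw_prs(aligned.aligned_dosage(m), aligned.betas, aligned.imputed_dosages)
            for i, sid in enumerate(m.subjects):
                assert raw[i] == pytest.approx(prs_oracle(m, panel, sid), abs=1e-12)

    def test_representation_invariance(self):
        """Re-expressing every panel entry on the opposite allele (negated
        beta, complementary frequency) leaves predicted risk unchanged."""
        rng = np.random.default_rng(13)
        m, panel = _random_instance(rng, n_snps=30)
        flipped = [
            WeightPanelEntry(e.variant_id, e.other_allele, e.effect_allele,
                             -e.beta, 1.0 - e.effect_allele_freq)
            for e in panel
        ]
        model = RiskModel(beta_prs=1.3, prs_norm_mean=0.0, prs_norm_sd=1.0)
        covs = [CovariateRecord(s, 70.0, "female", "E3E3") for s in m.subjects]
        a = score_cohort(m, panel, covs, model, normalization="cohort")
        b = score_cohort(m, flipped, covs, model, normalization="cohort")
        np.testing.assert_allclose(
            a["predicted_risk"], b["predicted_risk"], atol=1e-12
        )

    def test_missing_covariates_error_lists_subjects(self):
        rng = np.random.default_rng(17)
        m, panel = _random_instance(rng, n_subjects=3, n_snps=10)
        covs = [CovariateRecord("S0", 70.0, "female", "E3E3")]
        with pytest.raises(ValueError, match="S1"):
            score_cohort(m, panel, covs, RiskModel())
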
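"""Weighted polygenic risk scoring with a covariate logistic risk model.

The score is the sum of effect-allele dosages weighted by per-SNP effect
sizes (log-odds betas from an external GWAS), normalized to z units, then
passed with age, sex and APOE genotype through a pre-determined logistic
model to a predicted risk probability. Subjects are called high risk when
the predicted risk reaches the decision threshold (default 0.6).

Missing dosages contribute their population expectation ``2 * eaf``.
Panel/matrix allele orientation is harmonized before scoring; A/T and C/G
(strand-ambiguous) SNPs are excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_io import GenotypeMatrix, is_strand_ambiguous

logger = logging.getLogger(__name__)

APOE_GENOTYPES = ("E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4")

#: (#E4 alleles, #E2 alleles) per APOE genotype; E3E3 is the (0, 0) reference.
APOE_ALLELE_COUNTS: dict[str, tuple[int, int]] = {
    "E2E2": (0, 2),
    "E2E3": (0, 1),
    "E2E4": (1, 1),
    "E3E3": (0, 0),
    "E3E4": (1, 0),
    "E4E4": (2, 0),
}

SEX_CODES = {"female": 0.0, "male": 1.0}


@dataclass(frozen=True)
class WeightPanelEntry:
    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    effect_allele_freq: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ValueError(
                f"{self.variant_id}: effect_allele_freq "
                f"{self.effect_allele_freq} outside (0, 1)"
            )


@dataclass
class RiskModel:
    """Logistic risk model: logit(p) = intercept + beta_prs*z + covariates.

    ``z`` is the normalized PRS ``(raw - prs_norm_mean) / prs_norm_sd``.
    Sex is coded female=0 / male=1; APOE enters as counts of E4 and E2
    alleles (E3E3 reference). Not a clinical instrument: the default file
    shipped with this package is fitted on synthetic cohorts for tests and
    demonstrations only.
    """

    intercept: float = 0.0
    beta_prs: float = 1.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_apoe_e4: float = 0.0
    beta_apoe_e2: float = 0.0
    prs_norm_mean: float = 0.0
    prs_norm_sd: float = 1.0
    threshold: float = 0.6
    sex_coding: dict = field(default_factory=lambda: dict(SEX_CODES))
    age_center: float = 0.0

    def __post_init__(self) -> None:
        if self.prs_norm_sd <= 0:
            raise ValueError("prs_norm_sd must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        data = json.loads(Path(path).read_text())
        data.pop("description", None)
        return cls(**data)

    def to_json(self, path: str | Path, description: str | None = None) -> Path:
        path = Path(path)
        payload = asdict(self)
        if description:
            payload = {"description": description, **payload}
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


@dataclass(frozen=True)
class CovariateRecord:
    subject_id: str
    age: float
    sex: str
    apoe: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be > 0")
        if self.sex not in SEX_CODES:
            raise ValueError(f"{self.subject_id}: sex {self.sex!r} not female/male")
        if self.apoe not in APOE_GENOTYPES:
            raise ValueError(f"{self.subject_id}: unknown APOE genotype {self.apoe!r}")


def read_covariates(path: str | Path) -> list[CovariateRecord]:
    """Read a covariate TSV with columns subject_id, age, sex, apoe
    (extra columns such as diagnosis are preserved by callers that need
    them via pandas; this reader returns the typed records)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "age", "sex", "apoe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    return [
        CovariateRecord(r.subject_id, float(r.age), str(r.sex), str(r.apoe))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Weight panel
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "eaf")


def load_weight_panel(path: str | Path) -> list[WeightPanelEntry]:
    """Load a tab-separated weight panel with columns
    variant_id, effect_allele, other_allele, beta, eaf."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing panel columns {sorted(missing)}")
    entries: list[WeightPanelEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if row.variant_id in seen:
            raise ValueError(f"{path}:{i}: duplicate variant_id {row.variant_id!r}")
        seen.add(row.variant_id)
        try:
            beta = float(row.beta)
            eaf = float(row.eaf)
            if not np.isfinite(beta):
                raise ValueError("beta is not finite")
            entries.append(
                WeightPanelEntry(
                    str(row.variant_id),
                    str(row.effect_allele),
                    str(row.other_allele),
                    beta,
                    eaf,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: {exc}") from exc
    return entries


def write_weight_panel(entries: Sequence[WeightPanelEntry], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (e.variant_id, e.effect_allele, e.other_allele,
             repr(float(e.beta)), repr(float(e.effect_allele_freq)))
            for e in entries
        ],
        columns=PANEL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class AlignedPanel:
    """Panel entries matched to matrix columns with orientation resolved.

    ``aligned_dosage`` returns dosages counted toward each entry's effect
    allele (nan preserved for missing calls).
    """

    entries: list[WeightPanelEntry]
    matrix_column: list[int]
    flipped: list[bool]
    n_used: int = 0
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_absent: int = 0
    n_mismatched: int = 0

    @property
    def betas(self) -> np.ndarray:
        return np.array([e.beta for e in self.entries])

    @property
    def imputed_dosages(self) -> np.ndarray:
        return np.array([impute_missing_dosage(e) for e in self.entries])

    def aligned_dosage(self, m: GenotypeMatrix) -> np.ndarray:
        d = m.dosage[:, self.matrix_column].copy()
        flip = np.asarray(self.flipped)
        d[:, flip] = 2.0 - d[:, flip]
        return d

    def report(self) -> dict:
        return {
            "n_used": self.n_used,
            "n_flipped": self.n_flipped,
            "n_ambiguous": self.n_ambiguous,
            "n_absent": self.n_absent,
            "n_mismatched": self.n_mismatched,
        }


def align_panel(m: GenotypeMatrix, panel: Sequence[WeightPanelEntry]) -> AlignedPanel:
    """Match panel entries to matrix variants and resolve allele orientation.

    Matrix dosage counts allele_b. If the panel's (effect, other) alleles
    equal (allele_b, allele_a) the dosage is used as-is; if they equal
    (allele_a, allele_b) it is flipped d -> 2-d. Strand-ambiguous (A/T,
    C/G) SNPs are dropped, as are ids absent from the matrix and entries
    whose alleles match neither orientation.
    """
    index = m.variant_index()
    out = AlignedPanel(entries=[], matrix_column=[], flipped=[])
    for e in panel:
        if is_strand_ambiguous(e.effect_allele, e.other_allele):
            out.n_ambiguous += 1
            continue
        col = index.get(e.variant_id)
        if col is None:
            out.n_absent += 1
            continue
        v = m.variants[col]
        if (e.effect_allele, e.other_allele) == (v.allele_b, v.allele_a):
            flip = False
        elif (e.effect_allele, e.other_allele) == (v.allele_a, v.allele_b):
            flip = True
            out.n_flipped += 1
        else:
            out.n_mismatched += 1
            continue
        out.entries.append(e)
        out.matrix_column.append(col)
        out.flipped.append(flip)
        out.n_used += 1
    if out.n_used == 0:
        raise ValueError(
            "no panel SNPs overlap the genotype matrix "
            f"(absent={out.n_absent}, ambiguous={out.n_ambiguous}, "
            f"mismatched={out.n_mismatched})"
        )
    logger.info("panel alignment: %s", out.report())
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def impute_missing_dosage(entry: WeightPanelEntry) -> float:
    """Expected effect-allele dosage under Hardy-Weinberg: 2 * eaf."""
    return 2.0 * entry.effect_allele_freq


def raw_prs(dosages: np.ndarray, betas: np.ndarray, imputed: np.ndarray) -> np.ndarray:
    """Sum_i d_i * beta_i with missing dosages replaced by their imputed
    expectation. ``dosages`` is (n_subjects, n_snps) or (n_snps,)."""
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    filled = np.where(np.isnan(d), np.asarray(imputed, dtype=float), d)
    out = filled @ np.asarray(betas, dtype=float)
    return out if np.asarray(dosages).ndim == 2 else float(out[0])


def normalize_prs(raw, model: RiskModel):
    """(raw - prs_norm_mean) / prs_norm_sd."""
    return (np.asarray(raw, dtype=float) - model.prs_norm_mean) / model.prs_norm_sd


def cohort_norm_constants(raw_scores: np.ndarray) -> tuple[float, float]:
    """Cohort-standardization constants (mean, sample sd) of raw scores."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    sd = float(raw_scores.std(ddof=1))
    if sd == 0:
        raise ValueError("cohort PRS standard deviation is zero")
    return float(raw_scores.mean()), sd


def linear_predictor(z, cov: CovariateRecord, model: RiskModel) -> float:
    e4, e2 = APOE_ALLELE_COUNTS[cov.apoe]
    return (
        model.intercept
        + model.beta_prs * float(z)
        + model.beta_age * (cov.age - model.age_center)
        + model.beta_sex * SEX_CODES[cov.sex]
        + model.beta_apoe_e4 * e4
        + model.beta_apoe_e2 * e2
    )


def predicted_risk(z, cov: CovariateRecord, model: RiskModel) -> float:
    """Logistic inverse-link of the linear predictor; strictly in (0, 1)."""
    return float(expit(linear_predictor(z, cov, model)))


def classify_risk(p: float, threshold: float = 0.6) -> str:
    """'high' iff predicted risk >= threshold (boundary counts as high)."""
    return "high" if p >= threshold else "low"


def score_cohort(
    m: GenotypeMatrix,
    panel: Sequence[WeightPanelEntry],
    covariates: Sequence[CovariateRecord],
    model: RiskModel,
    normalization: str = "model",
) -> pd.DataFrame:
    """End-to-end scoring: align, sum, normalize, apply the logistic model.

    ``normalization`` is 'model' (use the model file's constants, the
    default for a pre-trained deployment) or 'cohort' (standardize to the
    analyzed cohort's mean/sd). Returns one row per subject:
    subject_id, raw_sum, normalized_prs, predicted_risk, risk_class,
    n_snps_used, n_snps_imputed.
    """
    cov_by_id = {c.subject_id: c for c in covariates}
    missing_cov = [s for s in m.subjects if s not in cov_by_id]
    if missing_cov:
        raise ValueError(f"subjects missing from covariates: {missing_cov}")

    aligned = align_panel(m, panel)
    d = aligned.aligned_dosage(m)
    n_imputed = np.isnan(d).sum(axis=1).astype(int)
    raw = raw_prs(d, aligned.betas, aligned.imputed_dosages)

    if normalization == "cohort":
        mean, sd = cohort_norm_constants(raw)
        z = (raw - mean) / sd
    elif normalization == "model":
        z = normalize_prs(raw, model)
    else:
        raise ValueError(f"unknown normalization mode {normalization!r}")

    rows = []
    for i, sid in enumerate(m.subjects):
        p = predicted_risk(z[i], cov_by_id[sid], model)
        rows.append(
            {
                "subject_id": sid,
                "raw_sum": raw[i],
                "normalized_prs": z[i],
                "predicted_risk": p,
                "risk_class": classify_risk(p, model.threshold),
                "n_snps_used": aligned.n_used,
                "n_snps_imputed": int(n_imputed[i]),
            }
        )
    return pd.DataFrame(rows)


def fit_risk_model(
    scores_z: np.ndarray,
    covariates: Sequence[CovariateRecord],
    labels: np.ndarray,
    threshold: float = 0.6,
    prs_norm: tuple[float, float] = (0.0, 1.0),
    age_center: float = 0.0,
) -> RiskModel:
    """Fit the logistic coefficients from (normalized PRS, covariates) to a
    binary high-risk label — used to build the package's demonstration
    model from synthetic cohorts. Unpenalized maximum likelihood."""
    from sklearn.linear_model import LogisticRegression

    X = np.column_stack(
        [
            np.asarray(scores_z, dtype=float),
            [c.age - age_center for c in covariates],
            [SEX_CODES[c.sex] for c in covariates],
            [APOE_ALLELE_COUNTS[c.apoe][0] for c in covariates],
            [APOE_ALLELE_COUNTS[c.apoe][1] for c in covariates],
        ]
    )
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    clf.fit(X, np.asarray(labels).astype(int))
    b = clf.coef_[0]
    return RiskModel(
        intercept=float(clf.intercept_[0]),
        beta_prs=float(b[0]),
        beta_age=float(b[1]),
        beta_sex=float(b[2]),
        beta_apoe_e4=float(b[3]),
        beta_apoe_e2=float(b[4]),
        prs_norm_mean=float(prs_norm[0]),
        prs_norm_sd=float(prs_norm[1]),
        threshold=threshold,
        age_center=age_center,
    )
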
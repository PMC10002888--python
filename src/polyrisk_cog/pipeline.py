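"""End-to-end pipeline: simulate/ingest -> QC -> score -> composite -> analysis.

``run_pipeline`` chains every stage on a synthetic cohort (or on files
produced elsewhere in the same formats) and writes all stage outputs plus
a run manifest sufficient to re-run bit-compatibly: paths, thresholds in
force, software version, seed, and per-stage record counts. Output files
contain no timestamps, so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import QCThresholds, apply_qc, read_genotypes
from .prs import (
    RiskModel,
    cohort_norm_constants,
    fit_risk_model,
    load_weight_panel,
    read_covariates,
    align_panel,
    raw_prs,
    score_cohort,
)
from .pacc import DEFAULT_BATTERY, fit_reference, long_to_wide, pacc_change, score_pacc
from .cohort import (
    build_cohort,
    compare_strata,
    label_decliners,
    roc_auc,
    timecourse,
)
from .simulate import SimulationConfig, simulate_cohort, write_fixture

logger = logging.getLogger(__name__)

DEFAULT_APOE_FILTER = ("E3E3", "E3E4")


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def train_risk_model(
    config: SimulationConfig,
    train_seed: int,
    qc_thresholds: QCThresholds | None = None,
) -> RiskModel:
    """Fit the demonstration RiskModel on an independently simulated
    training cohort: QC, align, raw scores, cohort-standardize, then
    unpenalized logistic regression of the true high-risk class on
    (normalized PRS, age, sex, APOE allele counts).

    The training cohort shares the analysis cohort's SNP architecture
    (same panel) but draws independent subjects from ``train_seed``. The
    resulting model file mirrors a pre-trained deployment: its
    normalization constants are the training cohort's raw-score mean/sd.
    Non-clinical; for tests and demonstrations only.
    """
    train = simulate_cohort(config, subject_seed=train_seed)
    qcd, _ = apply_qc(train.genotypes, qc_thresholds or QCThresholds())
    aligned = align_panel(qcd, train.panel)
    raw = raw_prs(aligned.aligned_dosage(qcd), aligned.betas, aligned.imputed_dosages)
    mean, sd = cohort_norm_constants(raw)
    z = (raw - mean) / sd
    labels = np.asarray(train.truth["subjects"]["high_risk"], dtype=bool)
    model = fit_risk_model(
        z,
        train.covariates,
        labels,
        threshold=0.6,
        prs_norm=(mean, sd),
        age_center=73.0,
    )
    return model


def run_pipeline(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    qc_thresholds: QCThresholds | None = None,
    risk_model: RiskModel | None = None,
    apoe_filter: Sequence[str] = DEFAULT_APOE_FILTER,
    decline_threshold: float = -1.0,
    horizon_months: int = 60,
) -> dict:
    """Run the full chain on a synthetic cohort and write all outputs.

    Stages: simulate -> write fixture -> re-ingest genotypes -> QC ->
    (train or load risk model) -> score -> composite -> cohort analysis.
    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    if seed is not None:
        cfg_dict = asdict(config)
        cfg_dict["seed"] = int(seed)
        config = SimulationConfig(**cfg_dict)
    qc_thresholds = qc_thresholds or QCThresholds()

    # --- simulate -----------------------------------------------------------
    cohort = _stage("simulate")(simulate_cohort)(config)
    fixture_paths = _stage("write_fixture")(write_fixture)(cohort, out / "fixture")

    # --- ingest + QC --------------------------------------------------------
    matrix = _stage("ingest")(read_genotypes)(fixture_paths["vcf"], "vcf")
    qcd, report = _stage("qc")(apply_qc)(matrix, qc_thresholds)
    report.write(out / "qc")

    # --- risk model ---------------------------------------------------------
    if risk_model is None:
        train_seed = (config.seed + 10_000_019) % 2**31
        risk_model = _stage("train_risk_model")(train_risk_model)(
            config, train_seed, qc_thresholds
        )
    risk_model.to_json(
        out / "risk_model.json",
        description=(
            "Demonstration logistic risk model fitted on a synthetic training "
            "cohort; sex coded female=0/male=1, APOE as E4/E2 allele counts "
            "(E3E3 reference), age centred at 73. Not a clinical instrument."
        ),
    )

    # --- scoring ------------------------------------------------------------
    panel = _stage("load_panel")(load_weight_panel)(fixture_paths["panel"])
    covariates = _stage("load_covariates")(read_covariates)(fixture_paths["covariates"])
    scores = _stage("score")(score_cohort)(qcd, panel, covariates, risk_model)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)

    # --- composite ----------------------------------------------------------
    def _pacc_stage():
        comp_long = pd.read_csv(fixture_paths["components"], sep="\t", dtype={"subject_id": str})
        wide = long_to_wide(comp_long)
        cov_df = pd.read_csv(fixture_paths["covariates"], sep="\t", dtype={"subject_id": str})
        cn_ids = set(cov_df.loc[cov_df["diagnosis"] == "CN", "subject_id"])
        baseline_cn = wide[(wide["visit"] == "bl") & wide["subject_id"].isin(cn_ids)]
        ref = fit_reference(baseline_cn, DEFAULT_BATTERY)
        ref.to_json(out / "reference_stats.json")
        scored = score_pacc(wide, ref, DEFAULT_BATTERY)
        scored.to_csv(out / "pacc_scores.tsv", sep="\t", index=False, na_rep="NA")
        changes = pacc_change(scored)
        changes.to_csv(out / "pacc_changes.tsv", sep="\t", index=False)
        return cov_df, changes

    cov_df, changes = _stage("pacc")(_pacc_stage)()

    # --- cohort analysis ----------------------------------------------------
    def _analysis_stage():
        frame = build_cohort(scores, changes, cov_df, apoe_filter=apoe_filter)
        tc_risk = timecourse(frame, "risk_class")
        tc_apoe = timecourse(frame, "apoe")
        tc_risk.to_csv(out / "timecourse_risk.tsv", sep="\t", index=False, na_rep="NA")
        tc_apoe.to_csv(out / "timecourse_apoe.tsv", sep="\t", index=False, na_rep="NA")
        comparisons = compare_strata(frame, "risk_class", ("high", "low"))
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        decl = label_decliners(frame, delta=decline_threshold, horizon_months=horizon_months)
        decl.to_csv(out / "decliners.tsv", sep="\t", index=False)
        roc = roc_auc(decl["predicted_risk"].to_numpy(), decl["decliner"].to_numpy())
        (out / "roc.json").write_text(json.dumps(roc.to_dict(), indent=2) + "\n")
        return frame, comparisons, decl, roc

    frame, comparisons, decl, roc = _stage("analyze")(_analysis_stage)()

    # --- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "thresholds": {
            "qc": asdict(qc_thresholds),
            "risk": risk_model.threshold,
            "decline": decline_threshold,
            "horizon_months": horizon_months,
            "apoe_filter": list(apoe_filter),
        },
        "counts": {
            "n_subjects": len(matrix.subjects),
            "n_variants_input": matrix.n_variants,
            "n_variants_retained": qcd.n_variants,
            "n_scored": int(len(scores)),
            "n_cohort_subjects": int(frame["subject_id"].nunique()),
            "n_decliner_labelled": int(len(decl)),
            "n_decliners": int(decl["decliner"].sum()),
        },
        "results": {
            "decliner_auc": roc.auc,
            "decliner_auc_ci": [roc.ci_low, roc.ci_high],
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
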
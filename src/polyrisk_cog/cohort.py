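"""Risk-stratified longitudinal analysis of cognitive composites.

Joins per-subject predicted risk, APOE genotype and baseline diagnosis
(CN / MCI) with the composite change-from-baseline trajectories, then
produces the study's outputs: per-visit timecourse tables by APOE or risk
stratum, Welch two-sample t-tests between strata at each visit, decliner
labels (composite change reaching -1 within the follow-up horizon), and
the decliner ROC/AUC with a DeLong 95% confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pacc import VISITS, VISIT_MONTHS

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    visit: str
    stratum_a: str
    stratum_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


@dataclass
class DeclinerROC:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(
    scores: pd.DataFrame,
    changes: pd.DataFrame,
    covariates: pd.DataFrame,
    apoe_filter: Sequence[str] | None = ("E3E3", "E3E4"),
) -> pd.DataFrame:
    """Join risk scores, covariates (with a ``diagnosis`` column) and
    change-from-baseline trajectories into one long cohort frame.

    Subjects are restricted to the requested APOE genotypes and to those
    with a scored baseline composite (i.e. present in ``changes`` or with
    zero follow-ups but a baseline). Returns a long frame with one row per
    (subject, follow-up visit with data): subject_id, diagnosis, apoe,
    sex, age, predicted_risk, risk_class, visit, change.
    """
    for col in ("subject_id", "predicted_risk", "risk_class"):
        if col not in scores.columns:
            raise ValueError(f"scores frame lacks column {col!r}")
    for col in ("subject_id", "diagnosis", "apoe"):
        if col not in covariates.columns:
            raise ValueError(f"covariates frame lacks column {col!r}")

    missing = set(scores["subject_id"]) - set(covariates["subject_id"])
    if missing:
        raise ValueError(
            f"subjects scored but absent from covariates: {sorted(missing)[:10]}"
        )

    merged = changes.merge(
        scores[["subject_id", "predicted_risk", "risk_class"]], on="subject_id"
    ).merge(
        covariates[[c for c in ("subject_id", "diagnosis", "apoe", "sex", "age") if c in covariates.columns]],
        on="subject_id",
    )
    n_before = merged["subject_id"].nunique()
    if apoe_filter is not None:
        merged = merged[merged["apoe"].isin(list(apoe_filter))]
        logger.info(
            "build_cohort: APOE filter %s kept %d of %d subjects",
            list(apoe_filter),
            merged["subject_id"].nunique(),
            n_before,
        )
    if merged.empty:
        raise ValueError("cohort is empty after APOE/baseline filtering")
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Timecourse and group comparison
# ---------------------------------------------------------------------------

def timecourse(cohort: pd.DataFrame, stratify_by: str = "risk_class") -> pd.DataFrame:
    """Per (visit, stratum) n / mean change / sd table (the shape of the
    participants-by-visit tables and timecourse figures).

    ``stratify_by`` is 'risk_class' or 'apoe' (any categorical column
    present in the cohort frame works). sd is NA for single-subject cells.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if stratify_by not in cohort.columns:
        raise ValueError(f"cohort lacks stratification column {stratify_by!r}")
    rows = []
    for (visit, stratum), grp in cohort.groupby(["visit", stratify_by], sort=False):
        ch = grp["change"].astype(float).dropna()
        rows.append(
            {
                "visit": visit,
                "stratum": stratum,
                "n": int(len(ch)),
                "mean_change": float(ch.mean()) if len(ch) else float("nan"),
                "sd_change": float(ch.std(ddof=1)) if len(ch) >= 2 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    order = {v: i for i, v in enumerate(VISITS)}
    return out.sort_values(
        ["visit", "stratum"], key=lambda s: s.map(order).fillna(s) if s.name == "visit" else s
    ).reset_index(drop=True)


def welch_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    visit: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Welch two-sample two-sided t-test (unequal variances), as R's
    ``t.test`` defaults: t statistic, Welch-Satterthwaite df, p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"welch_t needs n >= 2 per group, got {len(a)}, {len(b)}")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        visit=visit,
        stratum_a=labels[0],
        stratum_b=labels[1],
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def compare_strata(
    cohort: pd.DataFrame,
    stratify_by: str = "risk_class",
    strata: tuple[str, str] = ("high", "low"),
    visits: Sequence[str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch t-test between two strata at each follow-up visit.

    Per-visit p-values are unadjusted by default; ``holm`` adds a
    Holm-adjusted column. Visits with < 2 subjects in either stratum are
    skipped with a log message.
    """
    if visits is None:
        visits = [v for v in VISITS if v != "bl"]
    rows = []
    for visit in visits:
        sub = cohort[cohort["visit"] == visit]
        a = sub.loc[sub[stratify_by] == strata[0], "change"].to_numpy(dtype=float)
        b = sub.loc[sub[stratify_by] == strata[1], "change"].to_numpy(dtype=float)
        if (~np.isnan(a)).sum() < 2 or (~np.isnan(b)).sum() < 2:
            logger.info("compare_strata: skipping %s (insufficient n)", visit)
            continue
        r = welch_t(a, b, visit=visit, labels=strata)
        rows.append(vars(r))
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# Decliner labels and ROC
# ---------------------------------------------------------------------------

def label_decliners(
    cohort: pd.DataFrame, delta: float = -1.0, horizon_months: int = 60
) -> pd.DataFrame:
    """Label each subject a decliner iff any follow-up change at or before
    the horizon reaches ``delta`` (default: change <= -1 within 60 months).

    Subjects with no follow-up change inside the horizon are excluded
    (logged). Returns subject_id, decliner, min_change, predicted_risk.
    """
    month = cohort["visit"].map(VISIT_MONTHS)
    inside = cohort[(month > 0) & (month <= horizon_months)]
    rows = []
    for sid, grp in inside.groupby("subject_id", sort=False):
        ch = grp["change"].astype(float).dropna()
        if ch.empty:
            continue
        rows.append(
            {
                "subject_id": sid,
                "decliner": bool(ch.min() <= delta),
                "min_change": float(ch.min()),
                "predicted_risk": float(grp["predicted_risk"].iloc[0]),
            }
        )
    n_all = cohort["subject_id"].nunique()
    if len(rows) < n_all:
        logger.info(
            "label_decliners: excluded %d subjects without follow-up in horizon",
            n_all - len(rows),
        )
    return pd.DataFrame(rows)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> DeclinerROC:
    """AUC via the Mann-Whitney midrank construction (ties count one half)
    with a DeLong 95% confidence interval, truncated to [0, 1].

    The rank-sum form makes the negation symmetry AUC(s) + AUC(-s) = 1
    hold exactly in floating point.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("roc_auc requires both classes present")
    m, n = int(y.sum()), int((~y).sum())
    ranks = _midrank(s)
    auc = float((ranks[y].sum() - m * (m + 1) / 2) / (m * n))
    ci_low, ci_high = _delong_ci(s, y)
    return DeclinerROC(
        auc=auc, ci_low=ci_low, ci_high=ci_high, n_cases=m, n_controls=n
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values (structural
    components); normal-approximation CI truncated to [0, 1]. Degenerate
    (zero-variance) cases return the point estimate for both limits."""
    cases = scores[labels]
    controls = scores[~labels]
    m, n = len(cases), len(controls)
    all_ranks = _midrank(np.concatenate([cases, controls]))
    case_ranks = _midrank(cases)
    control_ranks = _midrank(controls)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement of each case among controls, and vice versa
    v10 = (all_ranks[:m] - case_ranks) / n            # P(control < case_i)
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m   # P(control_j < case)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    if var <= 0:
        return float(auc), float(auc)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    half = zcrit * math.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def plot_timecourse(tc: pd.DataFrame, path, title: str = "PACC change from baseline"):
    """Optional PNG timecourse plot (mean change ± sd per stratum)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for stratum, grp in tc.groupby("stratum"):
        months = grp["visit"].map(VISIT_MONTHS)
        order = np.argsort(months.to_numpy())
        ax.errorbar(
            months.to_numpy()[order],
            grp["mean_change"].to_numpy()[order],
            yerr=np.nan_to_num(grp["sd_change"].to_numpy()[order]),
            marker="o",
            capsize=3,
            label=str(stratum),
        )
    ax.set_xlabel("months from baseline")
    ax.set_ylabel("mean composite change")
    ax.set_title(title)
    ax.axhline(0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
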
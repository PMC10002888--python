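"""Modified PACC cognitive composite.

The Preclinical Alzheimer Cognitive Composite (PACC) is a sum of per-test
z scores. Each raw component score is standardized against the mean and
standard deviation of the baseline scores of the cognitively-normal (CN)
reference stratum, ``Z = (raw - mean(raw_bl)) / sd(raw_bl)``, reoriented
where necessary so that greater z always means better performance, and
summed. A composite requires at least two non-missing components;
otherwise it is NA. Timed components measured in seconds (Trails B) are
log-transformed before standardization.

The default four-component battery mirrors the modified ADNI composite:
a delayed-recall word-list score (higher = worse, i.e. errors), an
MMSE-style global score, a logical-memory episodic score, and a timed
executive component (DSST, or log Trails B as its proxy).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VISITS = ("bl", "m06", "m12", "m24", "m36", "m48", "m60")
VISIT_MONTHS = {"bl": 0, "m06": 6, "m12": 12, "m24": 24, "m36": 36, "m48": 48, "m60": 60}


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    higher_is_better: bool = True
    log_transform: bool = False


#: Modified-PACC default battery (log Trails B as the executive proxy).
DEFAULT_BATTERY: tuple[ComponentSpec, ...] = (
    ComponentSpec("adas_delayed_recall", higher_is_better=False),
    ComponentSpec("mmse", higher_is_better=True),
    ComponentSpec("logical_memory", higher_is_better=True),
    ComponentSpec("trails_b", higher_is_better=False, log_transform=True),
)


def battery_from_json(path: str | Path) -> tuple[ComponentSpec, ...]:
    specs = json.loads(Path(path).read_text())
    battery = tuple(ComponentSpec(**s) for s in specs)
    names = [s.name for s in battery]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate component names in battery: {names}")
    return battery


@dataclass
class ReferenceStats:
    """Frozen per-component baseline-CN mean/sd (computed after any log
    transform), with the reference n for auditability."""

    mean_bl: dict[str, float]
    sd_bl: dict[str, float]
    n_bl: dict[str, int]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {"mean_bl": self.mean_bl, "sd_bl": self.sd_bl, "n_bl": self.n_bl},
                indent=2,
            )
            + "\n"
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        d = json.loads(Path(path).read_text())
        return cls(mean_bl=d["mean_bl"], sd_bl=d["sd_bl"], n_bl=d["n_bl"])


def transform_raw(raw: float, spec: ComponentSpec) -> float:
    """Apply the component's transform; non-positive values for a
    log-transformed component are invalid and become missing."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return float("nan")
    if spec.log_transform:
        if raw <= 0:
            logger.warning(
                "%s: non-positive value %r for log-transformed component -> missing",
                spec.name,
                raw,
            )
            return float("nan")
        return math.log(raw)
    return float(raw)


def fit_reference(
    baseline_cn: pd.DataFrame, battery: Sequence[ComponentSpec] = DEFAULT_BATTERY
) -> ReferenceStats:
    """Fit per-component reference stats from baseline rows of the
    cognitively-normal stratum (wide table: one column per component).

    Sample statistics (n-1 denominator) on non-missing values, after any
    log transform. Raises when a component has fewer than two values or
    zero variance.
    """
    mean_bl: dict[str, float] = {}
    sd_bl: dict[str, float] = {}
    n_bl: dict[str, int] = {}
    for spec in battery:
        if spec.name not in baseline_cn.columns:
            raise ValueError(f"reference data lacks component {spec.name!r}")
        vals = baseline_cn[spec.name].astype(float).map(lambda x: transform_raw(x, spec))
        vals = vals.dropna()
        if len(vals) < 2:
            raise ValueError(
                f"component {spec.name!r}: need >= 2 baseline CN values, got {len(vals)}"
            )
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"component {spec.name!r}: zero baseline variance")
        mean_bl[spec.name] = float(vals.mean())
        sd_bl[spec.name] = sd
        n_bl[spec.name] = int(len(vals))
    return ReferenceStats(mean_bl, sd_bl, n_bl)


def component_z(raw: float, spec: ComponentSpec, ref: ReferenceStats) -> float:
    """z = (t(raw) - mean_bl) / sd_bl, negated for higher-is-worse
    components so greater z always means better performance. Missing raw
    propagates to missing z."""
    t = transform_raw(raw, spec)
    if math.isnan(t):
        return float("nan")
    z = (t - ref.mean_bl[spec.name]) / ref.sd_bl[spec.name]
    return z if spec.higher_is_better else -z


def compose(
    z_components: Mapping[str, float] | Sequence[float],
    min_components: int = 2,
    rescale: bool = False,
) -> tuple[float, int]:
    """Sum the available z components into the composite.

    Returns (composite, n_components_present); the composite is nan when
    fewer than ``min_components`` are present. With ``rescale`` the sum of
    the available components is scaled by battery_size / n_present
    (off by default: the composite is defined as the plain sum).
    """
    vals = list(z_components.values()) if isinstance(z_components, Mapping) else list(z_components)
    present = [v for v in vals if not (v is None or math.isnan(v))]
    n = len(present)
    if n < min_components:
        return float("nan"), n
    total = float(sum(present))
    if rescale and n:
        total *= len(vals) / n
    return total, n


def score_pacc(
    components: pd.DataFrame,
    ref: ReferenceStats,
    battery: Sequence[ComponentSpec] = DEFAULT_BATTERY,
    min_components: int = 2,
    rescale: bool = False,
) -> pd.DataFrame:
    """Score a wide component table (columns subject_id, visit, then one
    column per battery component) into per-subject-visit composites.

    Output columns: subject_id, visit, z_<component>..., composite,
    n_components_present.
    """
    required = {"subject_id", "visit"}
    if missing := required - set(components.columns):
        raise ValueError(f"component table lacks columns {sorted(missing)}")
    unknown_visits = set(components["visit"]) - set(VISITS)
    if unknown_visits:
        raise ValueError(
            f"unknown visit codes {sorted(unknown_visits)}; expected {VISITS}"
        )
    out = components[["subject_id", "visit"]].copy()
    zcols = {}
    for spec in battery:
        col = components[spec.name] if spec.name in components else np.nan
        zcols[f"z_{spec.name}"] = [
            component_z(v, spec, ref) for v in np.asarray(col, dtype=float)
        ] if spec.name in components else np.full(len(components), np.nan)
    for k, v in zcols.items():
        out[k] = v
    composites = []
    n_present = []
    zmat = out[[f"z_{s.name}" for s in battery]].to_numpy()
    for row in zmat:
        c, n = compose(list(row), min_components=min_components, rescale=rescale)
        composites.append(c)
        n_present.append(n)
    out["composite"] = composites
    out["n_components_present"] = n_present
    return out


def long_to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long component table (subject_id, visit, component, value)
    into the wide layout used by :func:`score_pacc`."""
    required = {"subject_id", "visit", "component", "value"}
    if missing := required - set(long_df.columns):
        raise ValueError(f"long component table lacks columns {sorted(missing)}")
    wide = long_df.pivot_table(
        index=["subject_id", "visit"], columns="component", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


def pacc_change(scored: pd.DataFrame) -> pd.DataFrame:
    """Change-from-baseline table.

    One row per subject and follow-up visit with a non-NA composite:
    subject_id, visit, composite, baseline_composite, change. Subjects
    with an NA baseline composite are excluded (logged); missing visits
    are simply absent (no interpolation).
    """
    rows = []
    excluded = []
    for sid, grp in scored.groupby("subject_id", sort=False):
        bl = grp.loc[grp["visit"] == "bl", "composite"]
        if bl.empty or math.isnan(float(bl.iloc[0])):
            excluded.append(sid)
            continue
        bl_val = float(bl.iloc[0])
        for _, r in grp[grp["visit"] != "bl"].iterrows():
            if math.isnan(float(r["composite"])):
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "visit": r["visit"],
                    "composite": float(r["composite"]),
                    "baseline_composite": bl_val,
                    "change": float(r["composite"]) - bl_val,
                }
            )
    if excluded:
        logger.info(
            "pacc_change: excluded %d subjects with NA baseline composite", len(excluded)
        )
    out = pd.DataFrame(rows, columns=["subject_id", "visit", "composite", "baseline_composite", "change"])
    out.attrs["excluded_baseline_na"] = excluded
    return out
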
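"""Synthetic ADNI-like cohort generator with planted ground truth.

Generates everything the pipeline consumes — biallelic SNP genotypes in
Hardy-Weinberg proportions, a matched effect-size weight panel, covariates
(age, sex, APOE genotype, baseline diagnosis), and longitudinal cognitive
component scores whose decline rate depends on a planted genetic
liability — so every stage is testable without restricted data.

Generative model
----------------
* Genotypes: per-SNP effect-allele frequency uniform on a configured
  range; dosages Binomial(2, f). Configurable fractions of SNPs are
  planted to violate each QC filter (excess missingness, rare MAF, forced
  heterozygote excess breaking Hardy-Weinberg).
* Liability: ``L = standardize( z_PRS + gamma_e4 * nE4 + gamma_age * (age - 73) )``
  where ``z_PRS`` is the cohort-standardized true weighted dosage sum.
* Risk class: Bernoulli(logistic(alpha + link_slope * L)); ``alpha`` is
  solved so the expected high-risk fraction matches the configured value.
* Trajectories: latent composite ``c(t) = c0 + slope * t + noise``, with
  baseline level by diagnosis (CN centred at 0, MCI shifted negative) and
  slope determined by (diagnosis, risk class); four component scores are
  carved from the composite so that each component's baseline-CN z scores
  have unit variance and the component z's sum back to the composite.
* Attrition: visits are missing at random with probabilities increasing
  over time; individual components are additionally masked at a small rate.

All draws flow from named sub-streams of one seed, so adding draws to one
stage never reorders another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .genotype_io import GenotypeMatrix, VariantRecord, write_dosage_table, write_vcf
from .prs import CovariateRecord, WeightPanelEntry, write_weight_panel
from .pacc import DEFAULT_BATTERY, VISITS, VISIT_MONTHS

_ARCH_STREAMS = ("architecture",)
_SUBJECT_STREAMS = ("genotypes", "covariates", "assignment", "trajectories", "masks")

#: raw-score location/scale per default battery component; higher-is-worse
#: components are reversed and trails_b is exponentiated back to seconds.
COMPONENT_SCALES = {
    "adas_delayed_recall": (3.0, 2.0),
    "mmse": (29.0, 1.2),
    "logical_memory": (13.0, 4.0),
    "trails_b": (4.5, 0.35),  # on the log-seconds scale
}

#: non-strand-ambiguous allele pairs assigned to simulated SNPs
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


@dataclass
class SimulationConfig:
    """Study-condition parameters, shaped on the published cohort tables."""

    n_subjects: int = 600
    n_snps: int = 500
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    beta_sd: float = 0.05  # per-SNP effect size sd (log-odds units)

    # covariates (cohort margins: age 73 (6.8), 363/652 male, Table-like APOE mix)
    age_mean: float = 73.0
    age_sd: float = 6.8
    age_range: tuple[float, float] = (55.0, 95.0)
    male_fraction: float = 363 / 652
    apoe_genotype_probs: dict = field(
        default_factory=lambda: {
            "E3E3": 0.57,
            "E3E4": 0.33,
            "E4E4": 0.07,
            "E2E4": 0.02,
            "E2E3": 0.008,
            "E2E2": 0.002,
        }
    )
    cn_fraction: float = 228 / 652  # CN at baseline; remainder MCI

    # liability -> risk
    gamma_e4: float = 0.8
    gamma_age: float = 0.02
    link_slope: float = 2.0
    high_risk_fraction: float = 0.6

    # trajectories (composite points; slopes per month)
    baseline_mean: dict = field(default_factory=lambda: {"CN": 0.0, "MCI": -5.5})
    baseline_sd: dict = field(default_factory=lambda: {"CN": 2.7, "MCI": 3.9})
    slope_per_month: dict = field(
        default_factory=lambda: {
            "CN:low": 0.2 / 60,
            "CN:high": -1.5 / 60,
            "MCI:low": -3.2 / 60,
            "MCI:high": -8.2 / 60,
        }
    )
    subject_slope_sd: float = 0.01  # per-subject slope heterogeneity, per month
    visit_noise_sd: float = 1.5  # composite measurement noise per visit

    # missingness / attrition
    call_missing_rate: float = 0.005
    missing_visit_prob: dict = field(
        default_factory=lambda: {
            "bl": 0.0,
            "m06": 0.03,
            "m12": 0.05,
            "m24": 0.10,
            "m36": 0.25,
            "m48": 0.28,
            "m60": 0.50,
        }
    )
    missing_component_prob: float = 0.02

    # planted QC violations (fraction of SNPs per filter)
    qc_violation_rates: dict = field(
        default_factory=lambda: {"missingness": 0.02, "maf": 0.02, "hwe": 0.02}
    )
    panel_flip_fraction: float = 0.5  # panel entries oriented to the other allele

    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.apoe_genotype_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("apoe_genotype_probs must sum to 1")
        if not all(0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("apoe_genotype_probs outside [0, 1]")
        if self.visit_noise_sd <= 0 or self.beta_sd <= 0:
            raise ValueError("all sds must be > 0")
        for v, p in self.missing_visit_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing_visit_prob[{v}]={p} outside [0,1]")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        data = json.loads(Path(path).read_text())
        for key in ("allele_freq_range", "age_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticCohort:
    """A complete simulated study with its ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix  # with call-level missingness applied
    true_dosages: np.ndarray  # complete dosage matrix (no missingness)
    panel: list[WeightPanelEntry]
    covariates: list[CovariateRecord]
    diagnosis: dict[str, str]  # subject -> CN/MCI
    components: pd.DataFrame  # long: subject_id, visit, component, value
    truth: dict

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [c.subject_id for c in self.covariates],
                "age": [c.age for c in self.covariates],
                "sex": [c.sex for c in self.covariates],
                "apoe": [c.apoe for c in self.covariates],
                "diagnosis": [self.diagnosis[c.subject_id] for c in self.covariates],
            }
        )


def _streams(seed: int, subject_seed: int | None = None) -> dict[str, np.random.Generator]:
    """Named sub-streams. The SNP architecture (frequencies, effect sizes,
    alleles, planted violations) is keyed to ``seed``; all subject-level
    draws are keyed to ``subject_seed`` (default: same), so independent
    cohorts can be drawn from one shared architecture."""
    arch = np.random.SeedSequence(seed).spawn(len(_ARCH_STREAMS))
    subj = np.random.SeedSequence(
        seed if subject_seed is None else subject_seed
    ).spawn(len(_SUBJECT_STREAMS) + 1)[1:]  # offset so subj streams != arch streams
    out = {n: np.random.default_rng(s) for n, s in zip(_ARCH_STREAMS, arch)}
    out.update({n: np.random.default_rng(s) for n, s in zip(_SUBJECT_STREAMS, subj)})
    return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig,
    arch_rng: np.random.Generator | None = None,
    subj_rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, list[WeightPanelEntry], dict]:
    """Simulate genotypes, the matching weight panel, and per-SNP truth.

    Returns (matrix-with-missingness, true_dosages, panel, snp_truth).
    Dosage counts allele_b; the panel's betas are oriented per entry (a
    configured fraction lists the opposite allele with negated beta, to
    exercise harmonization). Planted QC violations are disjoint SNP sets.
    The SNP architecture comes from ``arch_rng`` and the per-subject
    dosage/missingness draws from ``subj_rng``.
    """
    if arch_rng is None or subj_rng is None:
        streams = _streams(config.seed)
        arch_rng = arch_rng or streams["architecture"]
        subj_rng = subj_rng or streams["genotypes"]
    n, p = config.n_subjects, config.n_snps
    lo, hi = config.allele_freq_range
    freqs = arch_rng.uniform(lo, hi, size=p)

    rates = config.qc_violation_rates
    n_miss = int(round(rates.get("missingness", 0.0) * p))
    n_maf = int(round(rates.get("maf", 0.0) * p))
    n_hwe = int(round(rates.get("hwe", 0.0) * p))
    perm = arch_rng.permutation(p)
    planted = np.array(["none"] * p, dtype=object)
    idx_miss = perm[:n_miss]
    idx_maf = perm[n_miss : n_miss + n_maf]
    idx_hwe = perm[n_miss + n_maf : n_miss + n_maf + n_hwe]
    planted[idx_miss] = "missingness"
    planted[idx_maf] = "maf"
    planted[idx_hwe] = "hwe"
    freqs[idx_maf] = arch_rng.uniform(0.0005, 0.004, size=n_maf)
    miss_rate = np.full(p, config.call_missing_rate)
    miss_rate[idx_miss] = arch_rng.uniform(0.05, 0.20, size=n_miss)
    betas = arch_rng.normal(0.0, config.beta_sd, size=p)
    pair_idx = arch_rng.integers(0, len(_ALLELE_PAIRS), size=p)
    flip_panel = arch_rng.random(p) < config.panel_flip_fraction
    positions = np.sort(arch_rng.integers(10_000, 50_000_000, size=p))

    true_dosages = subj_rng.binomial(2, freqs[None, :], size=(n, p)).astype(float)
    true_dosages[:, idx_hwe] = 1.0  # forced heterozygote excess
    observed = true_dosages.copy()
    observed[subj_rng.random((n, p)) < miss_rate[None, :]] = np.nan

    subjects = [f"S{i + 1:04d}" for i in range(n)]
    variants = []
    panel = []
    for j in range(p):
        a, b = _ALLELE_PAIRS[pair_idx[j]]
        vid = f"rs{j + 1:06d}"
        chrom = str(j % 22 + 1)
        variants.append(VariantRecord(vid, chrom, int(positions[j]) + j, a, b))
        if flip_panel[j]:
            panel.append(
                WeightPanelEntry(vid, a, b, -betas[j], float(np.clip(1 - freqs[j], 1e-4, 1 - 1e-4)))
            )
        else:
            panel.append(
                WeightPanelEntry(vid, b, a, betas[j], float(np.clip(freqs[j], 1e-4, 1 - 1e-4)))
            )

    snp_truth = {
        "beta": betas.tolist(),
        "freq": freqs.tolist(),
        "planted": planted.tolist(),
        "planted_missingness_ids": [variants[j].variant_id for j in idx_miss],
        "planted_maf_ids": [variants[j].variant_id for j in idx_maf],
        "planted_hwe_ids": [variants[j].variant_id for j in idx_hwe],
    }
    matrix = GenotypeMatrix(subjects=subjects, variants=variants, dosage=observed)
    return matrix, true_dosages, panel, snp_truth


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    config: SimulationConfig,
    subjects: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[list[CovariateRecord], dict[str, str]]:
    """Draw age (truncated normal), sex and APOE genotype per subject,
    plus the baseline diagnosis stratum (CN / MCI)."""
    rng = rng or _streams(config.seed)["covariates"]
    n = len(subjects)
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")
    genotypes = sorted(config.apoe_genotype_probs)
    probs = np.array([config.apoe_genotype_probs[g] for g in genotypes])
    apoe = rng.choice(genotypes, size=n, p=probs / probs.sum())
    diag = np.where(rng.random(n) < config.cn_fraction, "CN", "MCI")
    covs = [
        CovariateRecord(sid, float(ages[i]), str(sexes[i]), str(apoe[i]))
        for i, sid in enumerate(subjects)
    ]
    return covs, {sid: str(diag[i]) for i, sid in enumerate(subjects)}


# ---------------------------------------------------------------------------
# Liability, risk class, analytic targets
# ---------------------------------------------------------------------------

def _n_e4(apoe: str) -> int:
    return apoe.count("E4")


def _age_trunc_moments(config: SimulationConfig) -> tuple[float, float]:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    mean, var = stats.truncnorm.stats(
        a, b, loc=config.age_mean, scale=config.age_sd, moments="mv"
    )
    return float(mean), float(var)


def liability_moments(config: SimulationConfig) -> tuple[float, float]:
    """Analytic mean and sd of the raw liability
    ``z_PRS + gamma_e4*nE4 + gamma_age*(age-73)`` under the config."""
    probs = config.apoe_genotype_probs
    e4_probs: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    for g, p in probs.items():
        e4_probs[_n_e4(g)] += p
    mean_e4 = sum(k * p for k, p in e4_probs.items())
    var_e4 = sum(k * k * p for k, p in e4_probs.items()) - mean_e4**2
    age_mean, age_var = _age_trunc_moments(config)
    mean = config.gamma_e4 * mean_e4 + config.gamma_age * (age_mean - 73.0)
    var = 1.0 + config.gamma_e4**2 * var_e4 + config.gamma_age**2 * age_var
    return mean, math.sqrt(var)


def _liability_grid(config: SimulationConfig, n_grid: int = 8001):
    """Grid density of the standardized liability (mixture over nE4)."""
    probs = config.apoe_genotype_probs
    e4_probs: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    for g, p in probs.items():
        e4_probs[_n_e4(g)] += p
    mean, sd = liability_moments(config)
    age_mean, age_var = _age_trunc_moments(config)
    cond_sd = math.sqrt(1.0 + config.gamma_age**2 * age_var) / sd
    grid = np.linspace(-10, 10, n_grid)
    dens = np.zeros_like(grid)
    for e, pe in e4_probs.items():
        if pe == 0:
            continue
        mu = (config.gamma_e4 * e + config.gamma_age * (age_mean - 73.0) - mean) / sd
        dens += pe * stats.norm.pdf(grid, loc=mu, scale=cond_sd)
    return grid, dens


def solve_link_intercept(config: SimulationConfig) -> float:
    """alpha such that E[logistic(alpha + link_slope * L)] equals the
    configured high-risk fraction."""
    grid, dens = _liability_grid(config)

    def frac(alpha: float) -> float:
        return float(np.trapezoid(expit(alpha + config.link_slope * grid) * dens, grid))

    return float(
        optimize.brentq(lambda a: frac(a) - config.high_risk_fraction, -30.0, 30.0)
    )


def analytic_risk_auc(config: SimulationConfig) -> float:
    """The generator's target AUC for recovering the true risk class from
    the liability: with class ~ Bernoulli(p(L)), the AUC of any monotone
    transform of L is ``E[p(L1)(1-p(L2)); L1 > L2] / (pi (1-pi))``.
    Computed by quadrature over the liability's mixture density."""
    alpha = solve_link_intercept(config)
    grid, dens = _liability_grid(config)
    p = expit(alpha + config.link_slope * grid)
    pi = float(np.trapezoid(p * dens, grid))
    # cumulative integral of (1-p) f below each grid point
    from scipy.integrate import cumulative_trapezoid

    below = cumulative_trapezoid((1 - p) * dens, grid, initial=0.0)
    num = float(np.trapezoid(p * dens * below, grid))
    return num / (pi * (1.0 - pi))


def assign_risk(
    config: SimulationConfig,
    true_dosages: np.ndarray,
    betas: np.ndarray,
    covariates: Sequence[CovariateRecord],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute standardized liabilities and draw the true risk classes."""
    rng = rng or _streams(config.seed)["assignment"]
    raw = true_dosages @ betas
    zprs = (raw - raw.mean()) / raw.std(ddof=1)
    lia_raw = np.array(
        [
            zprs[i] + config.gamma_e4 * _n_e4(c.apoe) + config.gamma_age * (c.age - 73.0)
            for i, c in enumerate(covariates)
        ]
    )
    mean, sd = liability_moments(config)
    liability = (lia_raw - mean) / sd
    alpha = solve_link_intercept(config)
    p_high = expit(alpha + config.link_slope * liability)
    high = rng.random(len(liability)) < p_high
    return liability, high


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def component_signal_sd(config: SimulationConfig) -> float:
    """sd of the iid component perturbations (before centring) chosen so
    each component's baseline-CN z score has unit variance."""
    var_c = config.baseline_sd["CN"] ** 2 + config.visit_noise_sd**2
    var_eta = 1.0 - var_c / 16.0
    if var_eta <= 0:
        raise ValueError(
            "baseline CN composite variance too large for unit-variance components"
        )
    return math.sqrt(var_eta / 0.75)  # centring 4 iid draws scales var by 3/4


def simulate_trajectories(
    config: SimulationConfig,
    covariates: Sequence[CovariateRecord],
    diagnosis: dict[str, str],
    high_risk: np.ndarray,
    rng: np.random.Generator | None = None,
    mask_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the longitudinal component table and per-subject truth.

    Returns (long component DataFrame, subject_truth dict). The latent
    composite declines linearly at the planted (diagnosis, risk) slope;
    components carve the composite into four unit-variance z scores and
    map them to raw instrument scales (Trails B in seconds, higher worse).
    """
    streams = None
    if rng is None or mask_rng is None:
        streams = _streams(config.seed)
    rng = rng or streams["trajectories"]
    mask_rng = mask_rng or streams["masks"]

    n = len(covariates)
    subjects = [c.subject_id for c in covariates]
    diags = np.array([diagnosis[s] for s in subjects])
    c0 = np.array(
        [
            rng.normal(config.baseline_mean[d], config.baseline_sd[d])
            for d in diags
        ]
    )
    slope = np.array(
        [
            config.slope_per_month[f"{diags[i]}:{'high' if high_risk[i] else 'low'}"]
            for i in range(n)
        ]
    )
    slope = slope + rng.normal(0.0, config.subject_slope_sd, size=n)
    eta_sd = component_signal_sd(config)
    battery = DEFAULT_BATTERY

    rows = []
    for v in VISITS:
        t = VISIT_MONTHS[v]
        noise = rng.normal(0.0, config.visit_noise_sd, size=n)
        comp = c0 + slope * t + noise
        eta = rng.normal(0.0, eta_sd, size=(n, len(battery)))
        eta -= eta.mean(axis=1, keepdims=True)
        z = comp[:, None] / len(battery) + eta
        visit_mask = mask_rng.random(n) < config.missing_visit_prob.get(v, 0.0)
        comp_mask = mask_rng.random((n, len(battery))) < config.missing_component_prob
        for i in range(n):
            if visit_mask[i]:
                continue
            for k, spec in enumerate(battery):
                if comp_mask[i, k]:
                    continue
                mu, sig = COMPONENT_SCALES[spec.name]
                val = mu + sig * (z[i, k] if spec.higher_is_better else -z[i, k])
                if spec.log_transform:
                    val = math.exp(val)
                rows.append(
                    {
                        "subject_id": subjects[i],
                        "visit": v,
                        "component": spec.name,
                        "value": float(val),
                    }
                )
    components = pd.DataFrame(rows)
    subject_truth = {
        "subject_id": subjects,
        "liability": None,  # filled by simulate_cohort
        "high_risk": high_risk.astype(bool).tolist(),
        "diagnosis": diags.tolist(),
        "baseline_level": c0.tolist(),
        "slope_per_month": slope.tolist(),
    }
    return components, subject_truth


# ---------------------------------------------------------------------------
# Orchestration and fixture output
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    subject_seed: int | None = None,
) -> SyntheticCohort:
    """Run the full generator under one seed (overrides ``config.seed``).

    ``subject_seed`` redraws the subjects (genotypes, covariates, risk
    classes, trajectories) while keeping the SNP architecture of ``seed``
    fixed — use it to draw independent train/held-out cohorts that share
    one weight panel.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": int(seed)})
    streams = _streams(config.seed, subject_seed)
    matrix, true_dosages, panel, snp_truth = simulate_genotypes(
        config, streams["architecture"], streams["genotypes"]
    )
    covariates, diagnosis = simulate_covariates(
        config, matrix.subjects, streams["covariates"]
    )
    betas = np.asarray(snp_truth["beta"])
    liability, high = assign_risk(
        config, true_dosages, betas, covariates, streams["assignment"]
    )
    components, subject_truth = simulate_trajectories(
        config, covariates, diagnosis, high, streams["trajectories"], streams["masks"]
    )
    subject_truth["liability"] = liability.tolist()
    truth = {
        "snps": snp_truth,
        "subjects": subject_truth,
        "analytic": {
            "high_risk_fraction": config.high_risk_fraction,
            "link_intercept": solve_link_intercept(config),
            "risk_auc_target": analytic_risk_auc(config),
        },
    }
    return SyntheticCohort(
        config=config,
        genotypes=matrix,
        true_dosages=true_dosages,
        panel=panel,
        covariates=covariates,
        diagnosis=diagnosis,
        components=components,
        truth=truth,
    )


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete fixture as plain-text files; re-reading them
    reproduces the in-memory objects exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(cohort.genotypes, out / "genotypes.vcf"),
        "dosage": write_dosage_table(cohort.genotypes, out / "genotypes.dosage.tsv"),
        "panel": write_weight_panel(cohort.panel, out / "weight_panel.tsv"),
        "covariates": out / "covariates.tsv",
        "components": out / "components.tsv",
        "truth": out / "ground_truth.json",
        "config": cohort.config.to_json(out / "sim_config.json"),
    }
    cohort.covariates_frame().to_csv(paths["covariates"], sep="\t", index=False)
    cohort.components.to_csv(paths["components"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2) + "\n")
    return paths
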
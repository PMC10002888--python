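# Methods

This note documents the statistical procedures, the synthetic-data
generative model, the parameter defaults and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Genotype quality control

Variants are filtered in a fixed order — call missingness, then minor
allele frequency (MAF), then Hardy–Weinberg equilibrium (HWE) — with MAF
and HWE computed on non-missing calls only. Thresholds are strict
inequalities on the failure side (fail iff missingness > 0.02, MAF <
0.01, HWE p < 10⁻⁶), so boundary values pass. The filter order is
recorded in the QC report's JSON summary so stage counts are auditable;
the per-variant table reports all three statistics and all three fail
flags for every variant, and a variant failing several filters is flagged
for each but removed once.

Degenerate cases are policy, not errors: an all-missing variant is
assigned MAF 0 (it fails the MAF filter and, except at permissive
thresholds, the missingness filter too), and a monomorphic variant has
HWE p = 1 (a single feasible configuration).

The HWE test is the two-sided conditional exact test: conditioning on the
allele counts, sum over every feasible heterozygote count the
probabilities no larger than the observed count's. Only the integer
weight `n! / (n_AA! h! n_BB!) · 2^h` varies with `h`, so the test is
evaluated in exact integer arithmetic with a single rational division at
the end: returned p-values are exact, with no tie-tolerance heuristics.
This costs more than the usual floating recurrence but is entirely
adequate at cohort scale (hundreds to a few thousand subjects) and makes
the test oracle-checkable to machine precision. A 1-df chi-square variant
is provided as an option but is not the default. Sample-level (per
subject) QC is deliberately not applied, and HWE is computed on all
subjects jointly rather than founders-only or stratified — the simplest
defensible contract for a single-cohort pipeline.

VCF is read through `cyvcf2`; phased and unphased calls are equivalent,
half-calls and non-diploid calls become missing, and multi-allelic sites
are skipped with a warning (the weight panel is biallelic). PLINK *text*
pairs (.ped/.map) are parsed directly (the binary .bed dialect is out of
scope); allele_b is taken as the observed minor allele, matching PLINK's
A1 convention, with ties broken alphabetically. A plain TSV dosage table
is the third dialect and the round-trip format; genotype coordinates are
1-based as in VCF.

## Scoring and the risk model

Panel–matrix harmonization compares (effect, other) alleles to the
matrix's (allele_b, allele_a): an exact match uses the dosage as-is, the
reverse match flips d → 2−d, strand-ambiguous A/T and C/G SNPs are
dropped deterministically (no frequency-based resolution), and ids that
are absent or allele-incompatible are dropped and counted. The score is
representation-invariant: re-expressing any panel entry on the opposite
allele (negated β, complementary frequency) leaves predicted risk
unchanged, a property the tests verify.

Missing dosages contribute their Hardy–Weinberg expectation 2f. The raw
sum is normalized either with constants carried in the model file (the
default — a pre-determined model implies training-time normalization) or
by cohort standardization (mean/sd of the analyzed cohort), selectable
per run. The logistic model's covariate coding is fixed and stored in
the model JSON so coefficients are unambiguous: sex female=0/male=1,
APOE as counts of E4 and E2 alleles with E3/E3 the (0,0) reference —
the most common parameterization, spanning all six genotypes — and age
optionally centred. The decision threshold is ≥ 0.6 on the predicted
probability, with the boundary counting as high risk; both the threshold
and the boundary convention live in the model file.

No clinically fitted coefficients ship with the package. The
demonstration model in `configs/default_risk_model.json` is an
unpenalized logistic fit on a synthetic training cohort (it is labelled
as such in its own description field) and is valid only with the weight
panel its architecture seed generates.

## The cognitive composite

The battery is configurable; the default mirrors the modified PACC used
with ADNI-style data: an ADAS delayed-recall word score (higher = worse),
an MMSE-style global score, a logical-memory episodic score, and a timed
executive component for which log-transformed Trails B substitutes when
DSST is unavailable. Reference statistics (sample mean and n−1 sd per
component, after the log transform) are fitted once on the baseline
cognitively-normal stratum, frozen, and serialized next to the results.
Trails B values ≤ 0 are invalid and become missing with a warning.

A composite is the plain sum of available z scores when ≥ 2 of the 4
components are present, else NA. No rescaling by 4/n_present is applied
by default — the composite is defined as a sum, and rescaling would
change the scale of change scores mid-trajectory — but a flag provides
it, and `n_components_present` is always reported. Change from baseline
is computed only at visits with a non-NA composite; subjects with an NA
baseline are excluded from change analyses and logged. Missing visits
are never interpolated.

## Group analysis

Group comparisons use Welch's unequal-variance two-sided t-test (the
default of R's `t.test`, through `scipy.stats.ttest_ind(equal_var=False)`),
reported with the Welch–Satterthwaite df. Per-visit p-values are
unadjusted by default, matching how such timecourses are conventionally
reported; a Holm adjustment column is available behind a flag.

A decliner is a subject whose change from baseline reaches −1 composite
points (boundary included) at *any* scheduled visit within the horizon
(default 60 months) — not only at the final visit, since attrition makes
final-visit-only labels fragile. The visit schedule is fixed to
{bl, m06, m12, m24, m36, m48, m60}.

AUC uses the Mann–Whitney midrank construction (ties count ½). The
rank-sum form was chosen over trapezoid ROC integration because it makes
the negation symmetry AUC(s) + AUC(−s) = 1 hold exactly in floating
point; the tests check it against both a pairwise-enumeration oracle and
`sklearn.metrics.roc_auc_score`. The 95% CI is DeLong's
placement-value variance with a normal approximation, truncated to
[0, 1]; the implementation reproduces R pROC's `ci.auc(method="delong")`
to 10 decimal places on a fixed instance frozen in the tests.

## The synthetic cohort generator

The generator emulates an ADNI-like longitudinal genetics study; its
defaults are fixed from the published shape of such cohorts and are the
package's study conditions, not tuning knobs.

**Genotypes.** Effect-allele frequencies uniform on [0.05, 0.95];
dosages Binomial(2, f) (Hardy–Weinberg proportions); per-call missingness
0.5%. Per filter, 2% of SNPs are planted violations: missingness rates
drawn from 5–20%, frequencies from 0.05–0.4%, or all calls forced
heterozygous. The weight panel covers every SNP with β ~ N(0, 0.05²);
half the entries are listed on the opposite allele (negated β,
complementary frequency) to exercise harmonization, and allele pairs are
drawn from the four non-ambiguous combinations. No linkage
disequilibrium is simulated — alignment and scoring do not require it at
this scale.

**Covariates.** Age ~ N(73, 6.8²) truncated to [55, 95]; male with
probability 363/652; APOE genotype probabilities E3E3 0.57, E3E4 0.33,
E4E4 0.07, E2E4 0.02, E2E3 0.008, E2E2 0.002; baseline diagnosis CN with
probability 228/652, else MCI.

**Liability and risk class.** The liability is the cohort-standardized
true weighted dosage sum plus 0.8 per E4 allele plus 0.02 per year of
age over 73, standardized by its analytic moments. The true high-risk
class is Bernoulli(logistic(α + 2·L)), with α solved by quadrature so
the expected high-risk fraction is 0.6. A deterministic threshold on L
was considered and rejected: it makes the class a function of observed
features, so any reasonable scorer separates it almost perfectly and
recovery checks degenerate. With the stochastic link, the generator has
an *analytic* AUC target — the AUC of any monotone transform of L,
computed by grid quadrature over L's mixture density (normal components
conditional on the E4 count; the truncated-normal age contribution is
treated as normal with its exact moments, an approximation that is
negligible at these parameter values). With the defaults the target is
≈ 0.862, and the acceptance suite verifies that a model fitted on one
cohort and applied to a held-out cohort sharing the SNP architecture
attains it within ±0.05.

**Trajectories.** A latent composite follows c(t) = c₀ + s·t + ε, with
baseline c₀ ~ N(0, 2.7²) for CN and N(−5.5, 3.9²) for MCI, visit noise
ε ~ N(0, 1.5²), per-subject slope jitter sd 0.01/month, and planted
monthly slopes summing over 60 months to +0.2 (CN low), −1.5 (CN high),
−3.2 (MCI low) and −8.2 (MCI high) composite points. Four component
z-scores carve up the composite as c/4 plus zero-sum perturbations whose
variance is chosen so each component's baseline-CN z has unit variance;
they are then mapped to instrument scales (errors reversed, Trails B
exponentiated to seconds). Two consequences worth noting: the component
z's sum back to the composite exactly, and refitting the reference on
the simulated baseline-CN stratum recovers ≈ (0, 1) per component, so
the scored composite tracks the latent one up to reference-sampling
wobble.

**Attrition.** Visits are missing completely at random with
probabilities rising over time (0, .03, .05, .10, .25, .28, .50 from
baseline to month 60, leaving ≈ half the cohort at month 60); individual
components are masked at 2%. Informative dropout is not modelled.

**Determinism.** All draws flow from named sub-streams of one seed, with
the SNP architecture (frequencies, betas, alleles, planted violations)
on its own stream keyed separately from subject-level draws. This gives
two guarantees: identical (config, seed) produce byte-identical fixture
files, and a `subject_seed` redraws subjects while holding the panel
fixed — which is what lets train and held-out cohorts share one
architecture. Output files contain no timestamps; two pipeline runs with
the same seed are byte-identical, verified by checksum in the tests.

## What the synthetic data does and does not show

Passing tests demonstrate the pipeline's internal correctness (each
statistic matches an independent oracle) and its ability to recover
planted structure under the stated conditions: missing-at-random
attrition, no LD, no population stratification, components that are
noisy linear slices of one latent composite, and a liability model whose
functional form matches the fitted one. They say nothing about effect
sizes in real cohorts, about robustness to informative dropout, practice
effects, platform batch effects, or miscalibration between the GWAS
panel's source population and the scored cohort. The decliner AUC
printed by the demonstration run (≈ 0.6 under the defaults) is a
property of the generator's noise and slope settings, not an estimate of
any real instrument's performance.

## Problem sizes

The default study conditions are 600 subjects × 500 SNPs. The
acceptance suite exercises 20 seeds of train/held-out pairs at that
size, the exact-HWE oracle sweep covers all genotype tables with n ≤ 50,
and the byte-identity check runs the full pipeline twice at 120 × 100.
These sizes were chosen so the whole suite completes in a couple of
minutes on one CPU while leaving every statistical check with comfortable
power.

## Known limitations

- The HWE implementation's exact arithmetic scales as O(n) big-integer
  operations per variant; for biobank-scale n a floating recurrence
  would be preferable.
- PLINK binary (.bed), genotype imputation, liftover, sex-chromosome
  handling and LD-aware panel construction are out of scope; the weight
  panel is taken as given, never estimated.
- The risk model is a configurable input; no published coefficient set
  is bundled.
- DeLong CIs use the normal approximation and can be degenerate when the
  placement variance is zero (both limits collapse to the estimate).
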
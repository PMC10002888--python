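# polyrisk-cog

Polygenic risk stratification of longitudinal cognitive decline.

`polyrisk-cog` is a tested, reusable implementation of the analysis chain
that takes raw genotypes and serial cognitive testing to a genetic risk
stratification of cognitive trajectories: per-variant quality control, an
allele-harmonized weighted polygenic risk score (PRS) passed with
covariates through a logistic risk model, a PACC-style cognitive
composite, high- versus low-risk group comparison over five years of
follow-up, and ROC analysis of "decliner" prediction. Because the
cohorts this kind of study draws on (e.g. ADNI) are access-controlled,
the package includes a first-class synthetic cohort generator with
planted ground truth, so the entire pipeline is testable and
demonstrable without any restricted data.

It is written for biostatisticians and genetic-epidemiology researchers
who want the pipeline pieces as an importable Python library (with a thin
`polyrisk-cog` CLI for shell use).

## The model

**Genotype QC.** A biallelic variant is retained iff

- call missingness ≤ 0.02,
- minor allele frequency ≥ 0.01,
- exact Hardy–Weinberg equilibrium p ≥ 10⁻⁶,

with equality always passing. The HWE test is the two-sided conditional
exact test: given allele counts $n_A, n_B$ in $n$ diploids, the
probability of $h$ heterozygotes is

$$P(h \mid n, n_A) = \frac{n!}{n_{AA}!\,h!\,n_{BB}!}\; \frac{2^{h}\, n_A!\, n_B!}{(2n)!},$$

and the p-value sums $P(h)$ over every feasible $h$ no more probable than
the observed count. The implementation uses exact integer arithmetic, so
p-values are exact rationals correctly rounded to float.

**PRS and predicted risk.** With effect-allele dosages $d_i \in \{0,1,2\}$
(missing calls imputed as $2f_i$, the population effect-allele frequency)
and external GWAS log-odds weights $\beta_i$,

$$\mathrm{PRS}_{\mathrm{raw}} = \sum_i d_i\,\beta_i,\qquad
z = \frac{\mathrm{PRS}_{\mathrm{raw}} - \mu}{\sigma},$$

$$\mathrm{risk} = \operatorname{logit}^{-1}\!\big(\alpha + \beta_{\mathrm{PRS}} z
 + \beta_{\mathrm{age}}\,\mathrm{age} + \beta_{\mathrm{sex}}\,\mathrm{sex}
 + \beta_{E4}\,n_{E4} + \beta_{E2}\,n_{E2}\big),$$

with APOE coded as counts of E4 and E2 alleles (E3/E3 reference) and
subjects called **high risk** when risk ≥ 0.6. Panel/genotype allele
orientation is harmonized (dosage flipped when the panel lists the other
allele); strand-ambiguous A/T and C/G SNPs are dropped.

**Cognitive composite.** Each component score is standardized against the
baseline cognitively-normal stratum, $Z = (raw - \bar{x}_{bl})/s_{bl}$,
reoriented so greater is better (timed tests are negated; Trails B is
log-transformed first), and summed. At least two of the four components
must be present, otherwise the composite is NA.

**Group analysis.** Change-from-baseline trajectories are compared
between strata with Welch's two-sided t-test per visit; a subject is a
*decliner* if their composite drops by ≥ 1 point at any visit within 60
months; the AUC of predicted risk for decliner status uses the
Mann–Whitney midrank construction with a DeLong 95% CI.

## Worked example

`examples/` holds one short narrative script per capability
(`01_genotype_qc.py` … `05_synthetic_cohort.py`). The end-to-end
analysis (`examples/04_risk_stratified_decline.py`) runs the default
synthetic study — 600 subjects (≈35% cognitively normal, 65% MCI), 500
SNPs, analysis restricted to APOE E3E3/E3E4 — and prints:

```
mean composite change from baseline by risk stratum:
stratum  high   low
visit
m06     -0.45 -0.05
m12     -1.03 -0.48
m24     -2.06 -1.08
m36     -3.02 -1.93
m48     -3.87 -2.66
m60     -4.93 -3.08

Welch high-vs-low comparisons per visit:
visit  n_a  n_b  mean_a  mean_b       t      p
  m06  290  228 -0.4505 -0.0507 -1.9561 0.0510
  ...
  m60  161  112 -4.9283 -3.0751 -3.7724 0.0002

decliner AUC 0.614 (DeLong 95% CI 0.544-0.683), 455 decliners / 81 stable.
```

High-risk subjects decline faster at every visit (1.9 composite points
more decline by month 60, p = 2×10⁻⁴), attrition shrinks the per-visit
n over time, and predicted risk ranks future decliners above chance.

The same chain is available from the shell:

```bash
polyrisk-cog simulate --config configs/default.json --out-dir fixture/
polyrisk-cog qc fixture/genotypes.vcf --format vcf --out-prefix qc/run
polyrisk-cog run --seed 1 --out-dir results_run/
```

`configs/` ships the default study conditions, a miniature CI-sized
configuration, and a documented demonstration risk model (fitted on
synthetic cohorts; not a clinical instrument).

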
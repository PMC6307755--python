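# Methods

This note records the statistical models, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing the
package's behaviour.

## Study shape and data model

The pipeline targets small two-assay cohorts: a normalized Beta-value
matrix (CpG probes × samples, entries in (0, 1)), a raw count matrix
(genes × samples), a probe manifest with genomic coordinates and
filter flags, a gene model with transcription start sites, and a sample
sheet recording tissue group (NINF / INF / STEN / nonCD), patient of
origin, culture passage (1–5), age, sex, medication flags, and smoking.
Patients contribute repeated samples (different passages and tissue
groups), and only a subset of samples is assayed on both platforms; the
default design has 18 methylation samples from 10 patients, 21
expression samples from 14 patients, and 9 samples from 6 patients in
both assays. All analyses treat the sample sheet as the source of truth
for design matrices and for the shared-sample intersection.

## Probe filtering and transforms

Probes are removed before modelling if their CpG overlaps a common SNP
(minor allele frequency > 0.05), if the probe is cross-reactive, or if
it maps to chrX/chrY (mixed-sex cohorts confound sex with methylation
there). Filtering is idempotent and reports counts per criterion.

Modelling uses M-values, M = log2(β/(1−β)), after clipping β to
[ε, 1−ε] with ε = 1e−6; the clip bound handles the occasional 0/1
entries in normalized matrices and is configurable. β-values are kept
for effect-size reporting (Δβ) and for the eQTM region means, where the
bounded scale is the interpretable one.

## PCA covariate screen

Principal components are computed on samples after per-feature
centering (no scaling — conventional for methylation and expression
screens, where features share a scale). For each covariate and each of
the leading components the screen reports Pearson r, r², p, and the
number of non-missing samples. Codings: disease degree is ordinal
NINF = 0 < INF = 1 < STEN = 2 with non-CD samples excluded from that
scale (a separate CD/non-CD indicator covers them); medication enters
both as per-drug indicators and as an any-medication flag. Both r and
r² are reported because signed correlations are informative and a
squared statistic cannot carry the sign. A constant covariate yields
r² = 0 with a warning rather than an error.

## Differential methylation

**Per-CpG models (DMPs).** For each probe, M is regressed on an
intercept, the group indicator for the requested contrast, and the
covariates. Fitting is a single vectorised least-squares across probes.
Covariate handling: missing ages are mean-imputed with a warning;
per-drug medication indicators collapse to one any-medication indicator
when they are collinear with the design (non-CD samples receive no
medication, so any CD vs non-CD contrast confounds the drug columns);
any remaining rank deficiency raises an error naming the collinear
columns.

**Patient blocking.** Repeated samples from one patient are handled by
generalized least squares under a block-equicorrelation structure with
one pooled intra-patient correlation ρ. ρ is estimated from the OLS
residuals by a projection-corrected moment estimator: since residuals
are e = (I−H)y, their cross-product matrix has expectation
σ²(A + ρ·A(B−I)A) with A = I−H and B the same-patient indicator; (σ²,
σ²ρ) are solved by least squares over the upper triangle and ρ is their
ratio. The naive pairwise residual correlation is biased by −H_ij at
these sample sizes (n ≈ 10–20, p ≈ 7) and can even flip sign; the
corrected estimator recovers ρ accurately in simulation (e.g. 0.50
estimated at true 0.50). ρ̂ outside (−0.3, 0.99) is clipped with a
warning. The design and data are then whitened by the inverse Cholesky
factor of the implied correlation matrix and refit.

**Variance moderation.** Residual variances are shrunk toward a pooled
prior by an empirical-Bayes scheme: s² is modelled as s₀²·F(d, d₀) and
(d₀, s₀²) are estimated by matching the mean and variance of log s²
(method of moments on the log scale, inverting the trigamma function by
Newton iteration). Moderated t-statistics use d + d₀ degrees of
freedom. With fewer than 50 probes the ordinary t is used — the prior
cannot be estimated stably from so few variances.

**Region calling (DMRs).** Seed CpGs are probes with raw p ≤ α_seed
(default 0.05). Seeds on one chromosome are clustered while consecutive
seeds lie within max_gap_bp (default 1000 bp); the cluster is then
extended to include the non-seed probes inside its span. A cluster must
contain at least min_cpgs = 3 seed probes (and hence ≥ 3 member CpGs).
Requiring the minimum on seeds rather than members is deliberate: two
nominal CpGs bridged by an uninformative interior probe would otherwise
qualify as a "3-CpG" region whose Stouffer score is computed on
selection-biased seeds, and region-level empirical FDR roughly doubles
past 0.2 in simulation; with the seed requirement, sensitivity for
planted regions (Δβ = 0.15, 8 CpGs, 10 vs 10) is ≥ 0.95 and empirical
FDR ≤ 0.05. The region statistic is Stouffer's combination of member
CpGs' signed z-scores, zᵢ = sign(effectᵢ)·Φ⁻¹(1−pᵢ/2), Z = Σzᵢ/√n,
two-sided; signing makes opposite-direction CpGs cancel, so a region
must be directionally coherent. BH adjustment runs across regions, and
significance is p_adj < 0.05. The original analysis used a
kernel-smoothing region caller; this package implements the stated
decision rule (≥ 3 CpGs, Stouffer, BH < 0.05) with seed-and-gap
clustering instead of reproducing kernel internals, whose parameters
are not part of the rule.

**Annotation.** Each region is assigned the gene whose TSS is nearest
the region midpoint; distance is 0 when the TSS falls inside the
region; ties break on the lexicographically smallest gene id.

## Differential expression

Genes with CPM < 1 in more than max_below samples are removed;
max_below defaults to ⌊n/2⌋ (11 of 21 in the default design), and the
rule is strictly "more than", so a gene below threshold in exactly
max_below samples is retained. Size factors are median-of-ratios:
factor_s = median over all-positive genes of counts[g,s] / geometric
mean_g. Note that only factor ratios are identified; the estimator
follows the usual convention of not rescaling (an option normalizes to
geometric mean 1), and scaling one sample's counts by c scales its
factor by c up to the c^(1/n) shift of the geometric-mean reference.

Each gene is fit with a negative-binomial log-linear model
(Var = μ + αμ²) with log size factors as fixed offsets and the same
covariate machinery as the methylation models. Dispersion: a Poisson
fit provides working means; α is then estimated by Cox–Reid-adjusted
profile maximum likelihood (the 0.5·log det(XᵀWX) penalty removes most
of the small-sample downward bias), floored at 1e−8 and capped at 20; a
parametric trend α(μ) = a₀ + a₁/μ is fit across genes by non-negative
least squares, and gene-wise log-dispersions are shrunk halfway toward
the trend (weight 0.5 — a fixed compromise between the noisy gene-wise
estimate at ~10–15 residual df and the trend; the weight is exposed).
The Wald statistic for the contrast coefficient is referred to the
standard normal, as is conventional for NB Wald tests. Under a null
simulation (α = 0.1, 10 vs 10, 2000 genes) the realized type-I error at
nominal 0.05 is ≈ 0.05. Non-converging genes are flagged, excluded from
BH, and counted in a warning. This is deliberately a minimal NB Wald
pipeline: no independent filtering, no fold-change shrinkage, plain BH
— the decision surface is the Wald p / BH output schema. A test
cross-checks the fold-change estimates against an independent reference
implementation (pydeseq2) on a small simulated dataset.

Log expression for integration is log2(count / size_factor + 1); the
pseudocount guards zeros and the base is configurable.

## eQTM integration

DMEGs are DMR–gene pairs where the region's nearest-TSS gene is a
significant DEG; a gene with several regions contributes one pair per
region. For each pair, over exactly the samples present in both assays
(9 in the default design):

- r = Pearson correlation of the region's unweighted mean β per sample
  with the gene's log₂ expression (≥ 3 shared samples and non-zero
  variance required; degenerate input is an error, never a silent 0).
- The 95% CI is the percentile bootstrap over B = 10 000 paired
  resamples; degenerate resamples are redrawn (counted; > 10·B redraws
  aborts). Percentile rather than BCa: it is the simplest method
  consistent with "B bootstraps", and the bounds can in pathological
  resamples exclude the point estimate, which is flagged rather than
  repaired.
- The permutation p compares |r| against null-DMRs: runs of exactly
  n_cpgs consecutive probes in the filtered manifest, drawn uniformly —
  without replacement when the pool has at least B runs, with
  replacement otherwise — excluding the observed region's own run
  (configurable). p = (1 + #{|r_null| ≥ |r_obs|}) / (B + 1), two-sided
  via |r| since each pair's null is conditioned on its own CpG count.
  Contiguous probe runs, not arbitrary coordinate windows, are the
  matched unit: they preserve the spatial correlation structure real
  regions have.

The pairwise co-expression screen reports Pearson correlations among a
gene set and flags pairs with |r| > 0.7; constant genes are dropped
with a warning.

## Metadata imputation

Age: a user-supplied linear clock (probe weights + intercept; clock
coefficient tables are published data and are not bundled — tests use
small synthetic clocks). The linear score s maps to years by the
inverse of the piecewise transform: age = (1+A)·exp(s) − 1 for s ≤ 0,
age = (1+A)·s + A otherwise, with adult age A = 20 by default. Missing
clock probes are imputed at the cohort mean β and counted; fewer than
50% present is an error listing the missing ids. After prediction the
clock CpGs are removed from the manifest so age-related probes cannot
confound the differential analyses.

Sex: from methylation, a sample is male when more than half of the
chrY probes show β ≥ 0.1 — female samples carry only
cross-hybridisation background (β below ~0.1) on chrY, while male chrY
probes span the usual bimodal range, so the detected fraction separates
near 0 vs ~0.75. The detection threshold is a documented operational
choice, not an inference of any published criterion. From expression, a
sample is male when at least 2 chrY genes exceed 1 CPM. Both callers
are deterministic, order-invariant, and report their margins.

## Synthetic-data generator

The generator is first-class, tested code; its defaults encode the
study conditions.

- **Manifest**: exponential inter-probe gaps (mean 500 bp) so that
  gap-based clustering behaves as on a real array; SNP /
  cross-reactive flags as independent Bernoulli draws (3% / 2%).
- **Cohort**: the default layout is an explicit table reproducing the
  study design, including patients contributing samples to several
  groups and one anonymous control patient whose age and sex are
  withheld (ground-truth columns `sex_true`/`age_true` are kept for
  verification). Demographics follow the study's patient table: CD age
  ~ N(35.7, 14.4), 60% male, 60% medicated, 20% smokers; controls
  ~ N(54.5, 18.3), 75% male, unmedicated. Generic designs assign
  samples to patients round-robin.
- **Methylation**: per-probe baselines from a two-component mixture of
  logit-normals (modes 0.1 / 0.9) mimicking array bimodality; a
  per-patient random effect (SD 0.15 on the M scale) plus residual
  noise (SD 0.35) — the patient effect is what makes blocking
  meaningful. Planted regions shift β additively in the target group,
  clipped into (0, 1). chrY probes carry only background (β in
  0.01–0.08) in female samples.
- **Counts**: NB with log-normal gene means (median 200, σ = 1.2),
  dispersion α = 0.1 by default, log-normal size factors (σ = 0.25);
  fold changes multiply the target group's mean by 2^lfc. chrY genes
  are silenced in females.
- **Coupling**: a shared standard-normal latent per shared sample is
  added to the region's β values and to the gene's log₂ counts with
  scales √(c·var) where c = |r|/(1−|r|), sign-flipped for negative
  targets, driving the realized correlation to c/(1+c) = |r|
  asymptotically. Constant baselines take small fixed injection scales
  (the link is then exactly linear); c is capped at 1e4 and counts stay
  integers, so |r| = 1 holds only up to rounding.

Not emulated: IDAT/FASTQ-level artefacts, probe chemistry (Type I/II),
batch and chip effects, detection-p missingness, and the four RNA
samples the study isolated but did not analyze. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to array/sequencing artefacts that
upstream QC and normalization are supposed to remove.

## Numerical choices and degenerate inputs

- p-values are clipped to [5e−324, 1]; BH ignores NaN entries.
- The trigamma inverse uses Newton iteration from standard starting
  values; non-positive excess log-variance yields an infinite prior df
  (complete shrinkage).
- Region calling on an empty DMP table returns an empty table, as does
  a pipeline run with zero DMEG pairs (success, empty eQTM report).
- Coordinate strings are 1-based inclusive `chrom:start-end`; readers
  accept an en-dash, writers emit a hyphen; BED exports are 0-based
  half-open with score −log10(p_adj) capped at 1000.
- All stochastic stages take explicit seeds; the pipeline derives
  per-stage seeds (< 2³¹) from one master seed via a seed sequence, and
  two runs with the same configuration are byte-identical.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run at sizes chosen to make
the Monte-Carlo bands tight enough to be informative while remaining
desk-scale: null calibration at 2 000 probes / 2 000 genes with 10 vs
10 samples; region recovery with four planted 8-CpG regions
(Δβ = 0.15) per seed over 20 seeds; fold-change recovery with 40
planted genes (lfc = 1); coupling-sign recovery over 100 study-shaped
cohorts (9 shared samples, target r = −0.8); bootstrap coverage over
500 replicates at B = 2 000; eQTM null uniformity over 200 uncoupled
pairs at B = 1 000; the exhaustive-vs-sampled null comparison on a
6-probe manifest at B = 10 000.

## Known limitations

- The GLS blocking uses a single pooled ρ for all probes, like the
  duplicate-correlation approach it approximates; probe-specific
  intra-patient correlation is not modelled.
- Dispersion-trend shrinkage uses a fixed weight rather than a
  likelihood-based posterior; at very small replicate numbers the Wald
  test inherits the usual plug-in optimism, visible as mild (< 1
  percentage point) excess type-I error in simulation.
- The permutation null conditions on CpG count but not on probe
  variance or genomic context (CpG-island status etc.).
- The headline counts of the motivating study (tens of thousands of
  DMPs, thousands of DMRs) are properties of the deposited patient
  data, which the desk-scale synthetic cohorts make no attempt to
  reproduce; verification is property-based (calibration, recovery,
  coverage) instead.
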
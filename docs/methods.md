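# Methods

`brainmeth` implements a cross-brain-region DNA methylation association
pipeline of the kind used for post-mortem case-control studies on
Illumina 450K-style arrays: quality control and normalization of beta
values, probe-wise association scans, cross-cohort meta-analysis, a
cross-region mixed model, spatially-aware region detection, a
permutation family-wise-error threshold, polygenic risk scoring, mQTL
mapping and GWAS-region enrichment.  This note records the model
assumptions, the defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## Data model

Beta values are methylation proportions in [0, 1], probes x samples,
with optional aligned detection-p and beadcount layers.  All coordinates
are 1-based; intervals are inclusive of both endpoints.  User-facing
effect sizes are percentage-point methylation differences (coefficient
x 100).  Missing values are explicit `NA` sentinels in every file
format, never zero.

## Quality control and normalization

The filters mirror the wateRmelon `pfilter` contract at the beta level:

- a sample is removed iff **more than** 1% of its probes have detection
  p > 0.01 (strict inequality);
- a probe is removed iff it has detection p > 0.05 in **at least** 1% of
  samples (inclusive) or beadcount < 3 in 5% of samples (inclusive);
- probes carrying any configured exclusion flag (SNP control probes,
  sex-chromosome, cross-hybridizing, SNP-proximal) are then dropped.

The order — samples first, then probes, then flags, then normalization —
follows the usual array-QC narrative; the alternative (probes first)
changes results only marginally and is not exposed.

True `dasen` normalization equalizes type-I/type-II intensity
distributions on the raw fluorescence scale.  Raw intensities are
outside this pipeline's data level, so normalization is between-sample
quantile normalization stratified by probe design type on betas: within
each type, each sample's values are replaced by the rank-matched
mean-of-sorted reference distribution (ties interpolate at the average
rank).  This preserves dasen's essential contract — type-stratified
distribution alignment across samples — and is a documented deviation
from the intensity-level original.

Sex checking is a 1-D two-cluster rule: per-sample mean methylation over
sex-chromosome probes is thresholded at the midpoint of the two
label-group means; disagreements are reported, never removed.

## Covariates

**Neuronal proportion** is the closed-form least-squares mixing weight of
a bulk profile between neuron and glia reference methylation profiles,

    p = clamp_[0,1] ( <x - mu_g, mu_n - mu_g> / ||mu_n - mu_g||^2 ),

a two-class constrained projection.  Reference profiles are a required
input file (the synthetic generator emits matched ones); multi-class
deconvolution is out of scope.  The cerebellum skips this covariate by
model configuration: its dominant granule neurons are NeuN-negative, so
NeuN-based deconvolution is invalid there.

**Methylation age** uses user-supplied clock coefficients (never
bundled).  The linear predictor L maps to years through the standard
clock calibration anchored at adult age A = 20: age = (1+A)·exp(L) − 1
for L ≤ 0 and (1+A)·L + A otherwise.  Age acceleration defaults to the
residual of methylation age on chronological age (a raw-difference mode
is available by flag, since the field uses both definitions); the group
contrast is a Welch t-test.

**Principal components** for the sensitivity analysis come from an SVD of
the probe-centered matrix with a deterministic sign convention (largest
magnitude loading positive), so results do not depend on row order or
LAPACK sign choices.

## Probe-wise association (EWAS)

Each probe's betas are regressed by OLS on the exposure (diagnosis coded
control = 0 / case = 1, or the polygenic score) plus covariates (age,
sex, neuronal proportion by default), with a two-sided t-test on the
exposure coefficient.  Betas, not M-values, are the default outcome (an
M-value switch exists).  Complete cases per probe model; probes that
cannot be fitted are flagged with a reason code, not dropped.  When the
design is shared across probes the scan is a single batched
least-squares solve, which is what keeps the permutation threshold and
the end-to-end runs fast.

The inflation factor is λ = χ²₁-quantile(1 − median p) / χ²₁-quantile(0.5);
QQ data (observed vs expected −log₁₀ p) are emitted alongside.  The PC
sensitivity analysis refits the scan with the top-k components appended
(k = 1..10) and reports the Pearson correlation of the per-probe
exposure estimates against the PC-free model.

## Meta-analysis and the cross-region model

Cohort pooling is fixed-effects inverse variance: θ̂ = Σwᵢθᵢ/Σwᵢ with
wᵢ = 1/seᵢ², se = (Σwᵢ)^(−1/2), normal z test, Cochran Q reported as a
diagnostic only.  With two cohorts the between-study variance cannot be
usefully estimated, so random-effects pooling is deliberately absent.
Two input flavors exist: direct (estimate, SE) pairs, and
covariate-adjusted group summaries, where "adjusted" means residualized
on the covariates only (grand mean re-added, group structure retained)
— the standard reading of metacont-style adjusted-means pooling; the
mean difference then carries the large-sample SE √(sd₁²/n₁ + sd₀²/n₀).

The cross-region model is a linear mixed model per probe: fixed effects
for the exposure, sex, age, neuronal proportion and brain bank; random
intercepts for donor and for brain region (REML variance components via
statsmodels MixedLM; non-negative by construction); Wald z on the
exposure with no small-sample df correction.  Region enters as a random
intercept even with only three levels — a fidelity-over-statistics
choice matching the modeling tradition this pipeline follows.  The
cerebellum is excluded by default because its global methylome is
distinct from the cerebral regions.  Constant covariate columns are
dropped from the design (they carry no information and break the
solver); non-convergent probes are flagged.

## Region detection

The DMR caller is a comb-p-style chain:

1. **ACF estimation** — Pearson correlation of z = Φ⁻¹(1 − p) over
   same-chromosome probe pairs in half-open distance bins ((0,50], ...,
   (250,300] bp); bins with fewer than 50 pairs carry 0 with a warning;
   negative estimates truncate to 0.
2. **Smoothing** — each probe's p is replaced by the Stouffer–Liptak
   combination over its ±300 bp neighbourhood, with the correlation
   matrix taken from the ACF at pairwise distances (step function, no
   interpolation; 0 beyond the last bin).  Switchable off, in which case
   seeding runs on raw p.
3. **Seeding** — maximal runs of probes with adjusted p < 1e-3 and
   consecutive gaps ≤ 300 bp; runs of fewer than 2 probes discarded.
4. **Scoring** — Stouffer–Liptak over the region's *raw* member
   p-values, C = Σzᵢ/√(1ᵀΣ1), combined p = 1 − Φ(C).
5. **Šidák correction** — p_sidak = 1 − (1 − p)^(n_a/n_r), computed in
   log space, where n_a is the genome-wide count of tested probes and
   n_r the region size.

z-transforms use the one-sided convention; p = 1 is clamped to
1 − 1e-16.  Under a global null with independent probes, measured over
150 seeds, significant region calls run at ~5% of candidate regions and
~0.03 per scan — i.e. the Šidák correction operates at its nominal
level; the corresponding validation test is a one-sided binomial check
of that rate, since the underlying counts are small.

## Permutation family-wise-error threshold

Diagnosis labels are permuted at the donor level (all of a donor's
samples move together, preserving the case:control donor counts), the
full scan is re-fit per permutation, and the minimum p recorded.  The
threshold is the lower empirical quantile — the ⌈α·n_perm⌉-th smallest
minimum.  On independent null probes this tracks the analytic
minimum-of-m-uniforms quantile 1 − (1−α)^(1/m).  The published constant
1.66e-7 for 450K-scale scans was derived by its authors from 5,000
permutations of an external 675-sample reference dataset; it ships here
as a citable default (`PUBLISHED_FWER_THRESHOLD`) and is reproducible
only with that external data — the procedure itself runs on any model
specification.

## Genetics

Genotype QC applies, in order: sample missingness > 5%, SNP missingness
> 1%, Hardy–Weinberg exact p < 1e-3, MAF < 5%.  The Hardy–Weinberg test
is the exact conditional (Levene–Haldane) distribution — the PLINK
default — summing probabilities of heterozygote counts no more likely
than observed; dosages are hard-called at a 0.1 threshold for counting.
When multiple samples share a donor, per-SNP statistics are computed on
one column per donor; replicated genotype columns would otherwise
distort the exact test.  LD pruning is a greedy positional scan dropping
the later SNP of any pair within 1500 bp with dosage r² > 0.20.

Polygenic scores are Σ dosage·weight over score-file SNPs matched by id,
with the dosage flipped (2 − d) when the score's effect allele is the
map's other allele; both PLINK scoring conventions (sum and
count-normalized mean) are provided, default sum.  The case-control
score contrast is a Welch t-test.

The mQTL scan regresses each probe on each SNP's dosage (additive
coding) plus the EWAS covariates, with the genome-wide threshold
3.69e-13 and the relaxed threshold 1e-10 both reported.  Monomorphic
SNPs in-sample are skipped with a reason.  GWAS-region enrichment is a
two-sided Fisher exact test (sum of hypergeometric probabilities no
larger than the observed table's) of DMP status (p < 1e-3) against
1-based inclusive interval membership, judged at the
Bonferroni-corrected level 1.25e-2.

## Synthetic data generator

The generator emulates the study design the pipeline targets: ~88
donors in two brain banks contributing up to four regions each (~262
samples), hippocampus restricted to one bank, cases ≈ 47% of donors,
ages ~N(60, 15²) truncated at 18, ~72% male.  Betas arise on the logit
scale as

    beta = invlogit( baseline + covariate terms + effects + noise )

with a bimodal baseline (mixture of low/high/intermediate components,
matching the U-shape of array methylation), an age slope of 0.004 logit
units/year, per-probe neuronal-proportion loadings (SD 0.3) on a latent
neuronal fraction ~N(0.40, 0.08²), per-probe cohort batch shifts (SD
0.05), a male shift of −1.0 logit on sex-chromosome-flagged probes, and
spatially correlated noise: a stationary Gaussian process per chromosome
with kernel exp(−d/φ), φ = 200 bp, marginal logit SD 0.3, sampled
exactly in O(n) via the kernel's Markov property.  Detection-p and
beadcount layers carry configurable failure rates (0.1% each).

Spiked effects are specified as beta-scale shifts; the generator
converts each to the logit offset that yields that expected shift at
the probe's baseline.  Spiked probes draw baselines in the
partially-methylated tails (~0.06–0.12, mirrored for negative effects):
that is where array DMPs are observed in practice, and it is the regime
in which a fixed beta-scale effect of 0.05 is large relative to
logit-scale biological noise — the regime the recovery experiments
assume.  mQTL-target probes carry a reduced residual logit SD of 0.1,
reflecting that strong cis-mQTLs explain most of a probe's variance
(which is what makes genome-wide mQTL thresholds like 3.69e-13
attainable at all).  Polygenic structure is injected by shifting causal
allele frequencies in cases so the expected case-control score
difference equals the requested multiple of the score SD; genotypes are
donor-level Hardy–Weinberg draws replicated across a donor's samples.

What the generator does **not** emulate: raw fluorescence intensities
and probe-chemistry bias beyond design-type labels, genotype imputation
uncertainty, LD beyond explicitly constructed blocks, cell-type mixtures
beyond two classes, and batch structure beyond additive cohort shifts.
Passing recovery tests therefore demonstrate the statistical machinery
on data with the stated design, spatial correlation and noise scales —
not robustness to intensity-level artefacts or fine-grained population
structure.

## Validation experiment sizes

The validation suite (also driven by `scripts/acceptance.py`) uses:
Welch tests recomputed from the study's printed cohort age summaries;
closed-form oracle sweeps of ≤ 200 units; permutation calibration on
1,000 independent probes × 60 samples with 500 permutations × 10 seeds
and 500 fresh replicates; recovery on 2,000-probe, 40-per-group datasets
over 20 seeds (150 seeds for the null region-call rate); null
calibration with the median KS p over 5 datasets of 10,000 probes and λ
over 10 datasets of 20,000 probes; and an end-to-end determinism run on
a 20,000-probe, ~160-sample two-cohort bundle with 100 permutations in
the FWER step.  These sizes are the package's own choices for a
single-CPU validation run; every quantity is recomputed from scratch at
call time.

## Known limitations

- The beta-level quantile normalization is a stand-in for
  intensity-level dasen; datasets with strong dye or background effects
  need upstream intensity processing.
- OLS on beta outcomes has non-Gaussian, heteroskedastic residuals;
  p-values are approximately calibrated (the null KS and λ checks bound
  the deviation) but not exact, as in the practice this mirrors.
- The mixed model treats region as a random intercept with three
  levels; its variance component is weakly identified and should be
  read as a nuisance control, not an estimate of interest.
- Fisher/HWE exactness is per-test; no multiplicity handling beyond the
  stated Bonferroni and Šidák rules is provided.
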
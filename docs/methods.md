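# Methods

This note documents the models implemented in `alsblood`, the synthetic
data that exercises them, the numerical choices made where the design was
open, and what the tests do and do not establish about real data.

## Study design being modelled

The package targets a two-cohort whole-blood expression study of ALS:
cohort C1 (cases and controls on one bead-array platform) and cohort C2
(cases, controls and ALS-mimic disease controls, MIM, on a newer platform
with a partially overlapping gene panel). Raw data carry per-(gene, sample)
detection p-values; a subset of samples in the public series stores them
with inverted orientation (1 − P). Both cohorts show an index-ordered batch
effect. Cases additionally carry survival annotations (onset-to-death
times, censored for survivors).

## Preprocessing

**Detection-p repair.** A sample whose Spearman correlation between
detection p and intensity exceeds +0.90 is flipped (p → 1 − p); afterwards
all correlations are strongly negative. The operation is an involution on
the flipped subset. Constant-p samples are unrepairable and left unchanged
with a warning.

**Normexp background correction.** Intensities are modelled as
X = B + S with B ~ N(μ, σ²) background and S ~ Exp(α) signal. Parameters
are estimated per sample by maximum likelihood (Nelder–Mead on
(μ, log σ, log α)); because the likelihood is multimodal on some samples
the optimizer runs from a moment-matching and a quantile-based start and
keeps the better optimum, falling back to moments if both fail. The
corrected value is the posterior mean E[S | X = x], strictly positive and
monotone. The moment start floors σ at one fifth of the sample SD — the
raw skewness-based estimate can otherwise push the start into a degenerate
σ → 0 basin.

**Quantile normalization** maps each sample onto the mean of the order
statistics, with ties receiving the average of the tied order statistics;
the map is idempotent and rank-preserving.

**Probe collapsing** keeps, per gene, the probe with the highest mean
expression (ties: lexicographically smallest probe id). **Detection
filtering** keeps genes detected (p < 0.05) in strictly more than
⌊0.20·n⌋ samples. **Coding filter** keeps genes flagged as protein coding
(RefSeq NM_/NP_).

**ComBat.** Batch adjustment is the parametric empirical-Bayes
location/scale model, delegated to `scanpy.pp.combat` with biological
covariates (group, sex by default; categorical covariates are encoded as
drop-first indicators because a full one-hot would be collinear with the
batch design). A deliberate property of EB ComBat, verified against the
reference R implementation, is that it equalizes per-gene batch means only
up to a shrinkage residual when the standardized batch effects vary across
genes; exact equalization holds for the closed-form family where rows are
affine transforms of a common sample pattern with proportional shifts. The
tests therefore assert exactness on that family, a ≥5× attenuation of
batch F-statistics in the general case, and recovery of the clean matrix
up to the per-(gene, batch) mean component.

**Outliers.** Grubbs' test (two-sided, p = min(1, 2n·P(T > t))) on the
first two PC axes at α = 0.05, a single removal round by default — a
deliberately non-aggressive policy. PCA fixes each component's sign by
making its largest-magnitude gene loading positive.

**Platform harmonization.** Per-platform Z-scoring (sample SD, ddof = 1);
constant genes are set to 0 with a warning.

## Differential expression and meta-analysis

Expression is residualized on a 0/1 sex indicator (per-sex mean centering),
then a two-group moderated t is fit per gene. The variance prior (d₀, s₀²)
comes from moment matching of log sample variances against the scaled-F
sampling model (trigamma inversion by Newton); when the observed dispersion
of log variances is at or below its sampling minimum, d₀ = ∞ and the prior
variance is the geometric mean of the gene variances — chosen so that when
every gene has the same sample variance the moderated t reduces exactly to
the ordinary t. DEGs: FC > 1.10 or FC < 0.909 and BH FDR < 0.10, strict.

Cohorts are pooled per shared, detection-passing gene with
DerSimonian–Laird random effects; the meta p comes from the normal z test
of the pooled estimate, and BH is applied across meta p-values. The pooled
estimate always lies in the convex hull of the cohort estimates and τ² = 0
whenever Q ≤ k − 1.

## Enrichment and GWAS proximity

The rank-enrichment statistic is the mean over ranks of (cumulative set
fraction − diagonal), with a two-sided Wilcoxon rank-sum p; ties in the
score are broken by gene id for determinism. Fisher overlap uses the
two-sided exact test (scipy's minimum-likelihood convention) with a
Haldane-corrected odds ratio when a cell is zero.

Gene–locus distance is point-to-interval on 1-based inclusive gene spans
(0 inside the span). The resampling null draws equal-sized gene sets
without replacement and reports `(1 + #{null ≤ obs})/(n + 1)` — never zero.
Genes on chromosomes with no locus have undefined distance and are dropped
from both the observed set and the resampling pool. Cell-type assignment
takes the argmax of mean reference expression, with a detectability gate
(detection p < 0.05 if the reference carries detection p-values, otherwise
expression above the compendium's 10th-percentile floor) and a
first-in-canonical-order tie-break.

## Deconvolution scores

Signature selection is the two-stage rule (150 lowest-p elevated genes,
re-sort by FC, keep 100), with "elevated" floored at log₂FC > 10⁻⁹ so
numerically identical profiles cannot qualify. Weights generalize
√(101 − r)/10 to √(n+1−r)/√n for n-gene signatures. Scores renormalize
weights over the genes present in the matrix (coverage below 50% warns,
zero coverage errors). Composites are unweighted means of the myeloid
(DC, MP, MC, NP, PL, RBC, ES) and lymphoid (CD8, CD4, GDT, NK, B) scores;
the subgroup rule is applied verbatim with strict ±0.05 thresholds. The
altitude-style external signatures are scored with the same √rank scheme
(a flag selects equal weights).

## Diagnostics

`cv_split` draws disjoint class-balanced train/test sets (296/100 per class
by default, scaled proportionally when fewer samples exist). Gene ranking
and PCA are fit strictly on the training split; the permuted-label control
(accuracy confined to [0.47, 0.53]) is the leakage check. McNemar uses the
continuity-corrected chi-square with an exact-binomial fallback when
b + c < 25 (the two conventions differ slightly; the `exact` argument
selects one explicitly). The single-gene AUC is the midrank Mann–Whitney
statistic with a DeLong confidence interval and Youden-optimal cut.

## Survival

The Cox fitter implements the Efron tie-corrected partial likelihood with
analytic gradient and Hessian (Newton with step-halving); it matches
lifelines' coefficients, standard errors and log-likelihood to 1e−5 and
exists in-package because the genome-wide screen and the CV loops need
thousands of small fits. Expression enters standardized, so hazard ratios
are per SD. Clinical covariates are age, sex, bulbar onset and cohort (the
cohort indicator is dropped automatically for single-cohort data).

The signature chain filters to marginal P < 0.15, clusters candidates by
1 − Pearson r (average linkage, tree cut targeting ≈13.4 genes per group),
keeps the min-p gene per cluster (ties: larger |log HR|, then gene id) and
runs forward/backward stepwise selection by likelihood-ratio p at
enter/stay 0.15 with an oscillation guard. Note a structural property of
this chain: cluster representatives are minima of pre-filtered p-values, so
under a global null the stepwise stage will still admit many of them — the
selection is optimistic by construction, which is why the null calibration
of stepwise is stated for non-pre-selected candidate lists and the null CV
concordance check uses a fixed, non-outcome-selected gene set.

Concordance is Harrell's C by default (exhaustively testable;
ties in the score count one half); the Heagerty–Zheng incident/dynamic AUC
integrated with 2·f(t)·S(t) weights from the Kaplan–Meier estimate is
available as an option. `cv_survival` refits both base and full models per
training split; trials with too few test events are skipped and counted.
The AFT contrast fits a Weibull accelerated-failure-time model (lifelines)
and reports the predicted-median ratio between the 80th and 20th feature
percentiles, which for a planted coefficient β equals exp(β·(q₈₀ − q₂₀)).
`score_combination_search` drops exactly duplicated score columns inside a
combination (the information matrix would be singular), so a duplicated
score reduces to its singleton model with identical LRT results.

## The simulator

`generate_reference` plants disjoint marker blocks per cell type at
log₂(FC) + 0.5 elevation over a shared Uniform(5, 9) log₂ baseline with
Gaussian sample noise (SD 0.3), so marker mean contrasts exceed log₂(FC)
with a noise margin. `generate_cohorts` draws per-sample cell-type
proportions from a Dirichlet around realistic whole-blood means
(concentration 50; case multipliers NP×1.5, RBC×0.67 by default — the
composition effect sizes are chosen for testability, as no empirical values
exist to calibrate them), mixes the reference mean profiles on the linear
scale, and adds planted DEG effects (±0.5 log₂ on 50 genes), a sex effect,
per-gene batch shifts on contiguous sample-index blocks (SD 0.4), a per-gene
platform offset on C2 (SD 0.3) and Gaussian noise (SD 0.25). Sample order
is shuffled within cohorts so batch blocks are not confounded with disease
group. Detection p-values follow a decreasing sigmoid of intensity with
jitter applied on the intensity scale inside the sigmoid (additive noise on
the p scale would saturate at the tails and destroy the monotone
correlation the repair step relies on); ~30% of samples have p → 1 − p.

Survival times follow a Weibull proportional-hazards model (shape 1.5,
scale 4 years) whose log hazard is linear in age (+0.3/decade over 60),
male sex (+0.2), bulbar onset (+0.5) and five planted genes (±0.5 per SD).
The planted genes are drawn from non-marker, detectably expressed genes:
marker genes carry composition-driven variance shared across whole blocks,
which would smear the planted hazard over hundreds of correlated genes, and
undetected genes would be removed by the screen's detection filter before
the signal could be found. The hazard uses batch-centered expression —
patients' biology, not measurement artifacts, drives survival. Censoring is
uniform with the upper bound calibrated by bisection to the configured
fraction (±5 points); zero censoring yields all-events data.

GWAS loci are placed with a configurable fraction within a maximum offset
of target genes (inside the gene span at offset 0) and the rest uniform
over chromosomes.

Default sizes are roughly one quarter of the motivating study (C1: 60
ALS / 120 CTL; C2: 40 ALS / 35 CTL / 20 MIM; 2,000-gene panels sharing
1,800), so the full pipeline runs in well under a minute; the
survival-focused experiments enlarge the case count to 400. These sizes are
the package's standard test conditions.

## What passing tests show — and what they do not

The simulator reproduces the statistical structure of the study —
mixtures over cell types, platform panels, index-ordered batches, inverted
detection p-values, covariate-driven Weibull survival — but not bead-level
artifacts, probe sequence effects, population stratification, realistic
gene–gene regulatory correlation beyond the compositional kind, or the
actual effect-size spectrum of ALS blood. Recovery results (100% planted
DEG recall, ρ ≈ 0.95 score fidelity, 5/5 survival genes) therefore validate
the implementation under its stated model, not the expected performance on
GEO data; the study's own headline numbers depend on the real cohorts and
are out of scope here.

## Interface note

The package is used from Python: the public functions plus the `examples/`
scripts are the interface, and `scripts/acceptance.py` is the single
runnable entry point for reproducing the headline numbers.
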
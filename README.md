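# alsblood

Blood transcriptome analysis toolkit for ALS (amyotrophic lateral
sclerosis) case–control cohorts: two-cohort bead-array normalization and
batch repair, cross-platform random-effects differential-expression
meta-analysis, immune cell-type signature scoring, GWAS-proximity
resampling tests, cross-validated diagnostic classification, and multigene
survival-signature derivation — together with a ground-truth simulator that
reproduces the statistical structure of such a study so every stage can be
validated against known planted effects.

## Who this is for

Researchers analysing whole-blood expression in ALS (or any case–control
disease cohort measured on two partially overlapping array platforms) who
want the full chain — from raw bead-array intensities with detection
p-values to DEG lists, cell-type scores, diagnostic accuracy and survival
signatures — as tested, composable Python functions rather than a fixed
script.

## The statistics at the core

- **Moderated t differential expression.** Per gene, a two-group linear
  model with empirical-Bayes variance shrinkage: the posterior variance is
  `s²_post = (d₀s₀² + d s²)/(d₀ + d)` with the prior `(d₀, s₀²)` estimated by
  moment matching on the log sample variances; `t = Δ/(s_post·c)` is referred
  to a t distribution on `d₀ + d` df. DEGs satisfy FC > 1.10 or FC < 0.909
  at Benjamini–Hochberg FDR < 0.10 (strict inequalities).
- **Random-effects meta-analysis.** Cohort log₂ fold changes are pooled with
  DerSimonian–Laird weights `w* = 1/(SE² + τ²)`,
  `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))`.
- **Cell-type signature scores.** For each of 12 blood cell types (NP, MC,
  DC, MP, PL, RBC, ES, CD4, CD8, GDT, B, NK), the 150 lowest-p elevated
  genes from a purified reference compendium are re-ranked by fold change
  and truncated to 100; rank *r* receives weight `√(101−r)/10`, and a
  sample's score is the weighted mean of its Z-scored expression. Myeloid
  and lymphoid composites thresholded at ±0.05 define patient subgroups.
- **GWAS proximity.** Point-to-interval base-pair distance from each gene to
  its nearest susceptibility locus; an empirical p-value
  `(1 + #{null ≤ obs})/(n_trials + 1)` from resampling equal-sized random
  gene sets (10,000 trials).
- **Diagnostics.** Class-balanced train/test resampling; genes ranked by
  training-set moderated-t p; PCA fit on training samples only; logistic,
  random-forest or RBF-SVM classifiers; McNemar test of confusion-matrix
  marginal homogeneity.
- **Survival.** Covariate-adjusted (age, sex, onset site, cohort) Cox
  proportional-hazards screening with an in-package Efron-tie Newton fitter;
  correlation clustering (`1 − r` distance, average linkage) with one
  min-p representative per cluster; forward/backward stepwise selection at
  enter/stay P < 0.15; Harrell (or Heagerty–Zheng) concordance of held-out
  linear predictors; Weibull AFT predicted-median contrasts between the
  20th and 80th expression percentiles.

## Worked example

`examples/` contains one short script per capability. For instance, the
survival-signature derivation at the scaled study conditions (400 cases,
2,000 genes, 30% censoring):

```bash
$ python examples/06_survival_signature.py
screen: 1613 genes tested, 262 at P < 0.15, 20 cluster representatives, 16 selected
planted survival genes recovered: 5/5
CV concordance: base 0.589 vs full 0.759 (gain +0.170)
```

All 5 planted survival genes pass the screen → cluster → representative →
stepwise chain, and adding the selected signature to the clinical covariates
raises the cross-validated probability of correctly ordering two held-out
patients' survival times from 0.59 to 0.76. Likewise,
`examples/02_preprocess_and_de.py` prints the number of detection-p-flipped
samples repaired, the per-cohort empirical-Bayes prior df, the meta DEG
counts and the planted-DEG recall (100% at the default effect size), and
`examples/03_celltype_scores.py` shows the neutrophil and erythroid scores
tracking the simulated cell fractions (Spearman ρ ≈ 0.95–0.98) and
separating cases from controls (rank-sum p ≈ 10⁻²⁴).

## Layout

- `src/alsblood/synthdata.py` — ground-truth simulator (`SimulationConfig`,
  `generate_reference`, `generate_cohorts`, `generate_survival`,
  `generate_gwas`)
- `src/alsblood/preprocess.py` — detection-p repair, normexp background
  correction, quantile normalization, probe collapsing, detection and
  coding-gene filters, ComBat, PCA/Grubbs outliers, per-platform Z-scores
- `src/alsblood/diffexpr.py` — sex residualization, moderated t, BH, DEG
  calling, DerSimonian–Laird pooling
- `src/alsblood/enrichment.py` — rank enrichment curves, Fisher overlap,
  cell-type assignment, GWAS proximity and resampling null, external
  signature correspondence screen
- `src/alsblood/deconv.py` — signature selection, √rank-weighted scores,
  M1/M2 polarization, myeloid/lymphoid subgroups
- `src/alsblood/diagnostics.py` — single-gene AUC (DeLong CI), CV splits,
  PC features, classifiers, McNemar
- `src/alsblood/survival.py` — Efron Cox fitter, genome-wide screen,
  clustering, stepwise selection, concordance CV, AFT contrasts, predicted
  survival spread
- `src/alsblood/pipeline.py` — end-to-end orchestration
  (`run_pipeline`, `derive_survival_signature`)

See `docs/methods.md` for the models, parameter choices and limitations.
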
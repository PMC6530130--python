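"""Simulate the two-cohort blood expression study and inspect ground truth.

Builds a scaled two-cohort dataset (partially overlapping gene panels,
batch/platform structure, detection p-values, planted case effects and
survival outcomes) and prints what was planted.
"""

import alsblood as ab

cfg = ab.SimulationConfig(seed=1)
e1, e2, samples, genes, truth = ab.synthdata.generate_cohorts(cfg)
samples, truth = ab.synthdata.generate_survival(
    samples, ab.pipeline._combined(e1, e2), cfg, truth)

print(f"cohort C1: {e1.shape[0]} genes x {e1.shape[1]} samples")
print(f"cohort C2: {e2.shape[0]} genes x {e2.shape[1]} samples")
print(f"shared genes: {len(set(e1.gene_ids) & set(e2.gene_ids))}")
print(samples["group"].value_counts().to_dict(), "by disease group")
print(f"planted DEGs: {len(truth.planted_degs)} "
      f"(log2 effects +/-{cfg.deg_log2fc})")
print(f"samples with flipped detection p: {len(truth.flipped_samples)}")
als = samples[samples["group"] == "ALS"]
print(f"ALS survival: median {als['surv_time'].median():.2f} y, "
      f"{1 - als['event'].mean():.0%} censored")
print("planted survival genes:",
      {str(g): eff for g, eff in truth.planted_surv_genes.items()})
# Each ALS sample's expression is a mixture over 12 immune cell types whose
# proportions were shifted (neutrophils up, erythroid cells down), plus the
# direct DEG effects above; the survival times follow a Weibull hazard driven
# by age, sex, onset site and the planted genes.
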
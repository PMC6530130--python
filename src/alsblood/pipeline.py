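"""End-to-end orchestration: simulate -> preprocess -> DE -> meta ->
deconvolution -> enrichment -> diagnostics -> survival.

`run_pipeline` executes every stage on one simulated dataset at the scaled
default study conditions and (optionally) writes the tabular artifacts of
each stage to a directory.  It exists both as the package's smoke test and
as the template for applying the stages to real cohort matrices.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv, diagnostics, diffexpr, enrichment, preprocess, synthdata
from . import survival as surv
from .containers import ExpressionMatrix
from .synthdata import SimulationConfig


def _prep_cohort(expr: ExpressionMatrix, samples: pd.DataFrame, cohort: str):
    """Per-cohort preprocessing: detection-p repair, quantile normalization,
    ComBat batch adjustment, outlier screen."""
    meta = samples.set_index("sample_id")
    ids = [s for s in expr.sample_ids if meta.loc[s, "cohort"] == cohort]
    sub = expr.subset_samples(ids)
    sub, flipped = preprocess.orient_detection_pvalues(sub)
    sub = preprocess.quantile_normalize(sub)
    batch = meta.loc[ids, "batch"]
    covs = meta.loc[ids, ["group", "sex"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = preprocess.combat_adjust(sub, batch, covs)
    pcs = preprocess.pca_scores(sub, k=min(3, len(ids) - 1))
    outliers = preprocess.detect_outliers_grubbs(pcs, axes=2)
    if outliers.flagged_sample_ids:
        keep = [s for s in sub.sample_ids if s not in outliers.flagged_sample_ids]
        sub = sub.subset_samples(keep)
    return sub, flipped, outliers


def derive_survival_signature(
    als_expr: ExpressionMatrix,
    samples: pd.DataFrame,
    genes_per_group: float = 13.4,
    p_marginal: float = 0.15,
) -> dict:
    """Multigene survival-signature derivation chain.

    Genome-wide covariate-adjusted Cox screen, filter to marginal
    P < ``p_marginal``, correlation clustering at ~``genes_per_group`` genes
    per group, one representative per group, then forward/backward stepwise
    selection.  Returns the screen table, candidate list, representatives and
    the selected signature.
    """
    screen = surv.genomewide_cox_screen(als_expr, samples)
    candidates = screen[screen["p"] < p_marginal]["feature"].tolist()
    out = {"screen": screen, "candidates": candidates, "representatives": [],
           "selected": [], "stepwise": None}
    if len(candidates) < 2:
        return out
    n_groups = max(2, int(round(len(candidates) / genes_per_group)))
    clusters = surv.cluster_genes(als_expr, candidates, n_groups)
    reps = surv.select_representatives(clusters, screen)
    meta = samples.set_index("sample_id").loc[list(als_expr.sample_ids)]
    cov = surv.encode_covariates(meta.reset_index())
    if cov["cohort_c2"].nunique() < 2:
        cov = cov.drop(columns=["cohort_c2"])
    G = als_expr.values.loc[reps].T
    G = (G - G.mean()) / G.std(ddof=1)
    sw = surv.stepwise_cox(G, cov, meta["surv_time"].to_numpy(),
                           meta["event"].to_numpy(dtype=int))
    out.update({"representatives": reps, "selected": sw.selected,
                "stepwise": sw, "clusters": clusters})
    return out


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    diag_trials: int = 200,
    surv_trials: int = 100,
    gwas_trials: int = 2000,
    diag_method: str = "logistic",
    seed: int | None = None,
) -> dict:
    """Run every stage on one simulated dataset; returns a results dict.

    When ``out_dir`` is given, each stage writes its TSV/JSON artifacts
    there.  ``seed`` overrides ``config.seed``.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    results: dict = {"config_seed": config.seed}

    # --- simulate ---------------------------------------------------------
    # one reference compendium drives both the cohort mixtures and the
    # downstream signature selection, as in the real study where the
    # compendium measures the same cell populations that make up blood
    n_union = config.n_genes_c1 + config.n_genes_c2 - config.n_shared
    reference, ref_truth = synthdata.generate_reference(
        n_genes=n_union, markers_per_type=config.ref_markers_per_type,
        marker_fc=config.ref_marker_fc,
        samples_per_type=config.ref_samples_per_type,
        noise_sd=config.ref_noise_sd, seed=config.seed + 3)
    expr_c1, expr_c2, samples, genes, truth = synthdata.generate_cohorts(
        config, reference, ref_truth)
    samples, truth = synthdata.generate_survival(samples, _combined(expr_c1, expr_c2),
                                                 config, truth)
    inc_truth = [g for g, e in truth.planted_degs.items() if e > 0]
    loci = synthdata.generate_gwas(
        genes, inc_truth, n_loci=config.n_loci,
        near_fraction=config.near_fraction, max_offset_bp=config.max_offset_bp,
        seed=config.seed + 2)
    truth.loci_target_genes = inc_truth

    # --- preprocess -------------------------------------------------------
    prep_c1, flipped1, out1 = _prep_cohort(expr_c1, samples, "C1")
    prep_c2, flipped2, out2 = _prep_cohort(expr_c2, samples, "C2")
    results["n_flipped_repaired"] = len(flipped1) + len(flipped2)
    results["n_outliers"] = len(out1.flagged_sample_ids) + len(out2.flagged_sample_ids)

    meta_samples = samples.set_index("sample_id")

    # --- per-cohort DE + meta --------------------------------------------
    de_tables = {}
    masks = {}
    for name, prep in (("C1", prep_c1), ("C2", prep_c2)):
        ids = list(prep.sample_ids)
        mask = preprocess.detection_filter(prep)
        masks[name] = mask
        resid = diffexpr.residualize_sex(prep, meta_samples.loc[ids, "sex"])
        de, info = diffexpr.moderated_ttest(resid, meta_samples.loc[ids, "group"])
        de_tables[name] = de
        results[f"d0_{name}"] = info.d0
    shared = [g for g in de_tables["C1"].index
              if g in de_tables["C2"].index
              and masks["C1"].get(g, False) and masks["C2"].get(g, False)]
    meta_table, inc_degs, dec_degs = diffexpr.meta_pipeline(
        de_tables["C1"], de_tables["C2"], shared)
    results["n_meta_genes"] = len(meta_table)
    results["n_increased_degs"] = len(inc_degs)
    results["n_decreased_degs"] = len(dec_degs)
    results["deg_recall"] = (
        sum(g in set(inc_degs) | set(dec_degs) for g in truth.planted_degs)
        / len(truth.planted_degs))

    # --- harmonized matrix (platform Z-scores) ----------------------------
    shared_genes = [g for g in prep_c1.gene_ids if g in set(prep_c2.gene_ids)]
    combined = _combined(prep_c1.subset_genes(shared_genes),
                         prep_c2.subset_genes(shared_genes))
    platform = meta_samples.loc[list(combined.sample_ids), "platform"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr_z = preprocess.zscore_by_platform(combined, platform)

    # --- deconvolution ----------------------------------------------------
    signatures = [deconv.select_signature_genes(reference, ct)
                  for ct in reference.cell_types]
    scores = deconv.compute_signature_scores(expr_z, signatures)
    group = meta_samples.loc[scores.index, "group"]
    from scipy import stats as _st
    np_p = _st.mannwhitneyu(scores.loc[group == "ALS", "NP"],
                            scores.loc[group == "CTL", "NP"],
                            alternative="two-sided").pvalue
    results["np_score_shift_p"] = float(np_p)
    for ct in ("NP", "RBC"):
        rho = _st.spearmanr(truth.planted_props.loc[scores.index, ct],
                            scores[ct]).statistic
        results[f"{ct.lower()}_score_spearman"] = float(rho)
    comp = deconv.composite_scores(scores)
    als_ids = group.index[group == "ALS"]
    comp_als = comp.loc[als_ids] - comp.loc[als_ids].mean()
    subgroups = deconv.assign_subgroups(comp_als["myeloid"], comp_als["lymphoid"])
    results["n_myeloid"] = int((subgroups["subgroup"] == "myeloid").sum())
    results["n_lymphoid"] = int((subgroups["subgroup"] == "lymphoid").sum())

    # --- enrichment -------------------------------------------------------
    assignment = enrichment.assign_cell_types(list(meta_table.index), reference)
    enr = enrichment.assignment_enrichment(assignment, set(inc_degs),
                                           set(meta_table.index))
    results["top_celltype_increased"] = (
        str(enr.sort_values("p").iloc[0]["cell_type"]) if len(enr) else None)
    ranked_inc = meta_table.sort_values("meta_log2fc", ascending=False).head(
        max(len(inc_degs), 50))["gene_id"].tolist()
    universe = list(meta_table.index)
    prox = enrichment.gwas_proximity_overlap(
        ranked_inc, genes, loci, thresholds=[9_000, 31_000, 62_000, 125_000])
    null = enrichment.gwas_distance_null(
        ranked_inc, universe, genes, loci, n_trials=gwas_trials,
        seed=config.seed + 4)
    results["gwas_empirical_p"] = null.empirical_p
    results["gwas_observed_mean_bp"] = null.observed_mean

    # --- diagnostics ------------------------------------------------------
    cv = diagnostics.run_cv(expr_z, samples, method=diag_method,
                            n_genes=min(450, expr_z.shape[0]), pc_count=20,
                            n_trials=diag_trials, seed=config.seed + 5)
    results["diag_accuracy"] = cv.mean_accuracy
    results["diag_sensitivity"] = cv.mean_sensitivity
    results["diag_specificity"] = cv.mean_specificity
    results["diag_mcnemar_frac"] = cv.mcnemar_significant_fraction

    # --- survival ---------------------------------------------------------
    als = samples[samples["group"] == "ALS"]
    als_expr = expr_z.subset_samples([s for s in als["sample_id"]
                                      if s in expr_z.sample_ids])
    chain = derive_survival_signature(als_expr, samples)
    screen = chain["screen"]
    results["cox_frac_p_lt_05"] = screen.attrs["frac_p_lt_05"]
    selected = chain["selected"]
    results["n_signature_genes"] = len(selected)
    results["surv_recovery"] = (
        sum(g in selected for g in truth.planted_surv_genes)
        / max(1, len(truth.planted_surv_genes)))
    if selected:
        cvres = surv.cv_survival(als_expr, samples, selected,
                                 n_trials=surv_trials, seed=config.seed + 6)
        results["concordance_base"] = cvres.base_mean
        results["concordance_full"] = cvres.full_mean
        results["concordance_gain"] = cvres.gain

    # --- artifacts --------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        synthdata.write_dataset(out / "simulated", config, expr_c1, expr_c2,
                                samples, genes, truth, loci)
        for name, de in de_tables.items():
            de.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        meta_table.to_csv(out / "meta_de.tsv", sep="\t", index=False)
        scores.to_csv(out / "signature_scores.tsv", sep="\t", index_label="sample_id")
        deconv.signatures_to_tsv(signatures, out / "signatures.tsv")
        subgroups.to_csv(out / "subgroups.tsv", sep="\t", index_label="sample_id")
        enr.to_csv(out / "celltype_enrichment.tsv", sep="\t", index=False)
        prox.table.to_csv(out / "gwas_proximity.tsv", sep="\t", index=False)
        cv.trials.to_csv(out / "diagnostic_trials.tsv", sep="\t", index=False)
        screen.drop(columns=["feature"]).to_csv(out / "cox_screen.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump({k: v for k, v in results.items()
                       if isinstance(v, (int, float, str, type(None)))}, fh, indent=1)
    return results


def _combined(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices on their shared gene panel."""
    shared = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    a, b = expr_a.subset_genes(shared), expr_b.subset_genes(shared)
    values = pd.concat([a.values, b.values], axis=1)
    detp = None
    if a.detection_p is not None and b.detection_p is not None:
        detp = pd.concat([a.detection_p, b.detection_p], axis=1)
    return ExpressionMatrix(values, detp)
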
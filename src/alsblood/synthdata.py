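"""Ground-truth simulator for the two-cohort blood transcriptome study design.

Generates (i) a purified cell-type reference compendium with planted marker
genes, (ii) two case-control cohorts measured on partially overlapping gene
panels with platform offsets, index-contiguous batch shifts, sex effects and
detection p-values (some with flipped orientation), (iii) Weibull survival
outcomes for cases driven by clinical covariates and a planted gene set, and
(iv) GWAS locus geometry placed preferentially near a target gene set.

Group effects are realised primarily as cell-type composition shifts: each
sample's expression is the log2 of a proportion-weighted linear-scale mixture
of reference cell-type profiles, so that deconvolution scores downstream have
a known target.  Direct differential-expression effects are added on top for
a planted gene list.  Every planted quantity is reported in a
:class:`~alsblood.containers.TruthRecord`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CELL_TYPES,
    CellTypeReference,
    ExpressionMatrix,
    GwasLociSet,
    TruthRecord,
    validate_sample_table,
)

# Approximate whole-blood composition used as the Dirichlet mean for controls.
BASE_PROPORTIONS = {
    "NP": 0.50, "MC": 0.08, "DC": 0.01, "MP": 0.01, "PL": 0.08, "RBC": 0.15,
    "ES": 0.03, "CD4": 0.06, "CD8": 0.04, "GDT": 0.01, "B": 0.015, "NK": 0.015,
}

N_CHROMS = 22
CHROM_LENGTH_BP = 100_000_000


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the scaled study conditions.

    Cohort sizes default to roughly one quarter of the study cohorts
    (C1: 60 ALS / 120 CTL; C2: 40 ALS / 35 CTL / 20 MIM) on 2,000-gene panels
    sharing 1,800 genes, so the full pipeline runs in minutes.
    """

    # cohort sizes
    c1_n_als: int = 60
    c1_n_ctl: int = 120
    c2_n_als: int = 40
    c2_n_ctl: int = 35
    c2_n_mim: int = 20
    # gene panels
    n_genes_c1: int = 2000
    n_genes_c2: int = 2000
    n_shared: int = 1800
    # technical structure
    noise_sd: float = 0.25              # per-(gene, sample) log2 noise
    batch_shift_sd: float = 0.4         # per-gene log2 batch offset scale
    batch_scale_jitter: float = 0.0     # optional multiplicative batch scale sd
    n_batches: int = 2
    platform_offset_sd: float = 0.3     # per-gene log2 offset on the C2 platform
    detection_flip_frac: float = 0.3    # fraction of samples with p -> 1 - p
    detection_slope: float = 1.5
    detection_noise: float = 0.3        # intensity-scale jitter inside the sigmoid
    # biological effects
    n_degs: int = 50
    deg_log2fc: float = 0.5             # planted case shift, alternating sign
    composition_multipliers: dict = field(
        default_factory=lambda: {"ALS": {"NP": 1.5, "RBC": 0.67}}
    )
    dirichlet_concentration: float = 50.0
    n_sex_genes: int = 20
    sex_effect: float = 0.5
    # survival model
    n_surv_genes: int = 5
    surv_log_hr: float = 0.5            # per SD of expression
    weibull_shape: float = 1.5
    weibull_scale: float = 4.0          # years
    censor_frac: float = 0.3
    beta_age: float = 0.3               # per decade over 60
    beta_sex: float = 0.2               # male vs female
    beta_onset: float = 0.5             # bulbar vs spinal
    # GWAS geometry
    n_loci: int = 215
    near_fraction: float = 0.5
    max_offset_bp: int = 9_000
    locus_target_count: int = 40
    # reference compendium
    ref_markers_per_type: int = 100
    ref_marker_fc: float = 4.0
    ref_samples_per_type: int = 20
    ref_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_flip_frac", "censor_frac", "near_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("c1_n_als", "c1_n_ctl", "c2_n_als", "c2_n_ctl",
                     "n_genes_c1", "n_genes_c2", "n_shared", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shared > min(self.n_genes_c1, self.n_genes_c2):
            raise ValueError("n_shared exceeds a cohort panel size")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def generate_reference(
    n_genes: int = 2400,
    cell_types: list[str] | None = None,
    markers_per_type: int = 100,
    marker_fc: float = 4.0,
    samples_per_type: int = 20,
    noise_sd: float = 0.3,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[CellTypeReference, TruthRecord]:
    """Simulate a purified cell-type compendium with planted marker genes.

    Each cell type receives ``markers_per_type`` disjoint marker genes whose
    log2 expression in that type is elevated by ``log2(marker_fc) + 0.5``
    over the shared baseline, so the planted mean contrast versus the pooled
    other types exceeds ``log2(marker_fc)`` with a margin covering sampling
    noise.  ``marker_fc == 1`` plants no signal.
    """
    if cell_types is None:
        cell_types = list(CELL_TYPES)
    if markers_per_type < 100:
        warnings.warn("markers_per_type >= 100 is recommended for stable signatures")
    if n_genes < len(cell_types) * markers_per_type:
        raise ValueError(
            f"n_genes={n_genes} cannot host {len(cell_types)} x {markers_per_type} "
            "disjoint markers"
        )
    if marker_fc < 1:
        raise ValueError("marker_fc must be >= 1")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    base = rng.uniform(5.0, 9.0, size=n_genes)
    elevation = 0.0 if marker_fc == 1.0 else np.log2(marker_fc) + 0.5

    # disjoint marker blocks, randomly placed
    perm = rng.permutation(n_genes)
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for t, ct in enumerate(cell_types):
        idx = perm[t * markers_per_type:(t + 1) * markers_per_type]
        marker_idx[ct] = idx
        marker_genes[ct] = [gene_ids[i] for i in idx]

    cols, types = [], []
    profiles = np.empty((n_genes, samples_per_type * len(cell_types)))
    j = 0
    for ct in cell_types:
        mean = base.copy()
        if elevation:
            mean[marker_idx[ct]] += elevation
        for s in range(samples_per_type):
            profiles[:, j] = mean + rng.normal(0.0, noise_sd, size=n_genes)
            cols.append(f"{ct}_{s:02d}")
            types.append(ct)
            j += 1
    prof = pd.DataFrame(profiles, index=gene_ids, columns=cols)
    ref = CellTypeReference(prof, pd.Series(types, index=cols))
    truth = TruthRecord(marker_genes={ct: list(v) for ct, v in marker_genes.items()})
    return ref, truth


def _dirichlet_proportions(rng, group: str, config: SimulationConfig,
                           cell_types: list[str]) -> np.ndarray:
    mean = np.array([BASE_PROPORTIONS.get(ct, 0.01) for ct in cell_types], dtype=float)
    for ct, mult in config.composition_multipliers.get(group, {}).items():
        mean[cell_types.index(ct)] *= mult
    mean = mean / mean.sum()
    if not np.isfinite(config.dirichlet_concentration):
        return mean          # degenerate limit: no compositional variation
    return rng.dirichlet(mean * config.dirichlet_concentration)


def _detection_p(rng, values: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Detection p as a noisy decreasing sigmoid of intensity.

    The jitter enters on the intensity scale inside the sigmoid, keeping the
    p-intensity relation strictly monotone up to small rank perturbations —
    the strong negative Spearman correlation the orientation-repair step
    assumes.  The midpoint is placed so that roughly 80% of genes clear the
    p < 0.05 detection threshold per sample.
    """
    x0 = np.quantile(values, 0.20) - np.log(19.0) / config.detection_slope
    jitter = rng.uniform(-config.detection_noise, config.detection_noise,
                         size=values.shape)
    p = 1.0 / (1.0 + np.exp(config.detection_slope * (values + jitter - x0)))
    return np.clip(p, 1e-9, 1.0 - 1e-9)


def _make_gene_table(rng, gene_ids: list[str]) -> pd.DataFrame:
    n = len(gene_ids)
    chrom = rng.integers(1, N_CHROMS + 1, size=n)
    length = rng.integers(2_000, 100_000, size=n)
    start = rng.integers(1, CHROM_LENGTH_BP - length.max(), size=n)
    coding = rng.random(n) < 0.9
    return pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": gene_ids,
        "coding": coding,
        "chrom": [f"chr{c}" for c in chrom],
        "start": start,
        "end": start + length - 1,       # 1-based inclusive
        "refseq_prefix": np.where(coding, "NM_", "NR_"),
    })


def generate_cohorts(
    config: SimulationConfig,
    reference: CellTypeReference | None = None,
    ref_truth: TruthRecord | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate the two cohorts on partially overlapping gene panels.

    Returns ``(expr_c1, expr_c2, sample_table, gene_table, truth)``.  Sample
    expression is ``log2`` of the proportion-weighted linear-scale mixture of
    the reference cell-type mean profiles, plus planted case effects, a sex
    effect, an additive per-gene batch shift on a contiguous sample-index
    block within each cohort, a per-gene platform offset on cohort C2, and
    Gaussian noise.  Detection p-values decrease with intensity; a configured
    fraction of samples has them flipped to ``1 - p``.
    """
    rng = np.random.default_rng(config.seed)
    n_union = config.n_genes_c1 + config.n_genes_c2 - config.n_shared
    gene_ids = [f"G{i:05d}" for i in range(n_union)]
    if reference is None:
        reference, ref_truth = generate_reference(
            n_genes=n_union,
            markers_per_type=config.ref_markers_per_type,
            marker_fc=config.ref_marker_fc,
            samples_per_type=config.ref_samples_per_type,
            noise_sd=config.ref_noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            gene_ids=gene_ids,
        )
    else:
        gene_ids = list(reference.profiles.index)
        n_union = len(gene_ids)
        if config.n_genes_c1 + config.n_genes_c2 - config.n_shared != n_union:
            raise ValueError("reference gene panel inconsistent with configured sizes")

    cell_types = reference.cell_types
    mean_linear = np.power(2.0, reference.mean_profiles()[cell_types].to_numpy())

    # panels: first n_shared genes shared, then cohort-private blocks
    shared = gene_ids[:config.n_shared]
    c1_only = gene_ids[config.n_shared:config.n_genes_c1]
    c2_only = gene_ids[config.n_genes_c1:]
    panel_c1 = shared + c1_only
    panel_c2 = shared + c2_only

    # planted direct DEGs drawn from the shared panel, alternating sign
    if config.n_degs > len(shared):
        raise ValueError("requested DEGs not in the shared panel")
    deg_genes = list(rng.choice(shared, size=config.n_degs, replace=False))
    deg_effects = {
        g: config.deg_log2fc * (1 if i % 2 == 0 else -1)
        for i, g in enumerate(deg_genes)
    }
    sex_genes = list(rng.choice(
        [g for g in shared if g not in deg_effects],
        size=config.n_sex_genes, replace=False))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    deg_vec = np.zeros(n_union)
    for g, eff in deg_effects.items():
        deg_vec[gene_pos[g]] = eff
    sex_vec = np.zeros(n_union)
    for g in sex_genes:
        sex_vec[gene_pos[g]] = config.sex_effect

    rows = []
    props = {}
    sample_counter = 0

    def _simulate_cohort(cohort: str, groups: list[tuple[str, int]], panel: list[str]):
        nonlocal sample_counter
        panel_idx = np.array([gene_pos[g] for g in panel])
        samples = []
        for group, n in groups:
            for _ in range(n):
                sid = f"S{sample_counter:04d}"
                sample_counter += 1
                sex = "M" if rng.random() < 0.6 else "F"
                age = float(np.clip(rng.normal(62, 10), 25, 90))
                onset = (
                    "bulbar" if (group == "ALS" and rng.random() < 0.3)
                    else ("spinal" if group == "ALS" else "NA")
                )
                samples.append((sid, group, sex, age, onset))
        # shuffle so that batch blocks (contiguous in sample index) are not
        # confounded with disease group
        samples = [samples[i] for i in rng.permutation(len(samples))]
        n_samp = len(samples)
        X = np.empty((len(panel), n_samp))
        for j, (sid, group, sex, age, onset) in enumerate(samples):
            p = _dirichlet_proportions(rng, group, config, cell_types)
            props[sid] = p
            mix = mean_linear @ p
            x = np.log2(mix)
            if group == "ALS":
                x = x + deg_vec
            if sex == "M":
                x = x + sex_vec
            if config.noise_sd > 0:
                x = x + rng.normal(0.0, config.noise_sd, size=n_union)
            X[:, j] = x[panel_idx]

        # contiguous index-ordered batch blocks with per-gene additive shifts
        batch_labels = np.empty(n_samp, dtype=object)
        bounds = np.linspace(0, n_samp, config.n_batches + 1).astype(int)
        for b in range(config.n_batches):
            lab = f"{cohort}_B{b + 1}"
            batch_labels[bounds[b]:bounds[b + 1]] = lab
            if config.batch_shift_sd > 0:
                shift = rng.normal(0.0, config.batch_shift_sd, size=len(panel))
            else:
                shift = np.zeros(len(panel))
            block = slice(bounds[b], bounds[b + 1])
            X[:, block] += shift[:, None]
            if config.batch_scale_jitter > 0:
                scale = np.exp(rng.normal(0.0, config.batch_scale_jitter, size=len(panel)))
                mu = X[:, block].mean(axis=1, keepdims=True)
                X[:, block] = mu + (X[:, block] - mu) * scale[:, None]

        if cohort == "C2" and config.platform_offset_sd > 0:
            X += rng.normal(0.0, config.platform_offset_sd, size=len(panel))[:, None]

        detp = np.empty_like(X)
        flipped = []
        sids = [s[0] for s in samples]
        flip_mask = rng.random(n_samp) < config.detection_flip_frac
        for j in range(n_samp):
            pj = _detection_p(rng, X[:, j], config)
            if flip_mask[j]:
                pj = 1.0 - pj
                flipped.append(sids[j])
            detp[:, j] = pj

        for (sid, group, sex, age, onset), batch in zip(samples, batch_labels):
            rows.append({
                "sample_id": sid, "cohort": cohort,
                "platform": "V3" if cohort == "C1" else "V4",
                "batch": batch, "group": group, "sex": sex, "age": age,
                "onset_site": onset, "surv_time": np.nan, "event": np.nan,
            })
        expr = ExpressionMatrix(
            pd.DataFrame(X, index=panel, columns=sids),
            pd.DataFrame(detp, index=panel, columns=sids),
        )
        return expr, flipped

    expr_c1, flipped1 = _simulate_cohort(
        "C1", [("ALS", config.c1_n_als), ("CTL", config.c1_n_ctl)], panel_c1)
    expr_c2, flipped2 = _simulate_cohort(
        "C2", [("ALS", config.c2_n_als), ("CTL", config.c2_n_ctl),
               ("MIM", config.c2_n_mim)], panel_c2)

    sample_table = pd.DataFrame(rows)
    gene_table = _make_gene_table(rng, gene_ids)
    truth = TruthRecord(
        planted_degs=deg_effects,
        planted_props=pd.DataFrame.from_dict(props, orient="index", columns=cell_types),
        marker_genes=dict(ref_truth.marker_genes) if ref_truth else {},
        flipped_samples=flipped1 + flipped2,
        sex_genes=sex_genes,
    )
    validate_sample_table(sample_table)
    return expr_c1, expr_c2, sample_table, gene_table, truth


def generate_survival(
    samples: pd.DataFrame,
    expr: ExpressionMatrix,
    config: SimulationConfig,
    truth: TruthRecord | None = None,
    surv_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Fill survival fields for ALS samples from a Weibull hazard model.

    The log hazard is linear in age (per decade over 60), sex, bulbar onset
    and the standardized expression of a planted gene set; censoring times
    are uniform with the upper bound calibrated so the realised censoring
    fraction matches ``config.censor_frac`` within 5 points.
    """
    rng = np.random.default_rng(config.seed + 1)
    als = samples.index[samples["group"] == "ALS"].tolist()
    als_ids = samples.loc[als, "sample_id"].tolist()
    if not als_ids:
        raise ValueError("no ALS samples to assign survival outcomes")
    present = [s for s in als_ids if s in expr.sample_ids]
    if len(present) != len(als_ids):
        raise ValueError("expression matrix missing ALS samples")

    if surv_genes is None:
        # avoid cell-type marker genes: their composition-driven variance is
        # shared across whole marker blocks, which would smear the planted
        # hazard over hundreds of correlated genes
        markers: set[str] = set()
        if truth is not None:
            for genes_of_type in truth.marker_genes.values():
                markers.update(genes_of_type)
        candidates = [g for g in expr.gene_ids if g not in markers]
        if expr.detection_p is not None:
            # survival genes should be expressed in patients: require
            # detection in a clear majority of case samples so the planted
            # signal survives downstream detection filters
            det = (expr.detection_p[als_ids].to_numpy() < 0.05).mean(axis=1)
            detected = set(np.asarray(expr.gene_ids)[det > 0.5])
            candidates = [g for g in candidates if g in detected]
        if len(candidates) < config.n_surv_genes:
            candidates = list(expr.gene_ids)
        surv_genes = list(rng.choice(candidates, size=config.n_surv_genes, replace=False))
    log_hrs = {g: config.surv_log_hr * (1 if i % 2 == 0 else -1)
               for i, g in enumerate(surv_genes)}

    # hazard is driven by the patient's biology, not by measurement
    # artifacts: remove additive batch/platform shifts by centering the
    # planted genes within batch before standardizing
    sub = expr.values.loc[surv_genes, als_ids].copy()
    batch_of = samples.set_index("sample_id").loc[als_ids, "batch"]
    for b in batch_of.unique():
        cols = batch_of.index[batch_of == b]
        sub[cols] = sub[cols].sub(sub[cols].mean(axis=1), axis=0)
    sub = sub.to_numpy()
    sd = sub.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    beta = np.array([log_hrs[g] for g in surv_genes])
    lp = beta @ z

    meta = samples.set_index("sample_id").loc[als_ids]
    lp = (
        lp
        + config.beta_age * (meta["age"].to_numpy() - 60.0) / 10.0
        + config.beta_sex * (meta["sex"] == "M").to_numpy()
        + config.beta_onset * (meta["onset_site"] == "bulbar").to_numpy()
    )

    u = rng.uniform(size=len(als_ids))
    times = config.weibull_scale * np.power(-np.log(u) * np.exp(-lp), 1.0 / config.weibull_shape)

    if config.censor_frac <= 0:
        obs, event = times, np.ones(len(times), dtype=int)
    else:
        lo, hi = 1e-6, float(times.max()) * 10
        cu = rng.uniform(size=len(times))
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = np.mean(cu * mid < times)
            if frac > config.censor_frac:
                lo = mid
            else:
                hi = mid
        cmax = 0.5 * (lo + hi)
        censor = cu * cmax
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)

    out = samples.copy()
    idx = out.index[out["sample_id"].isin(als_ids)]
    order = out.loc[idx, "sample_id"].map({s: i for i, s in enumerate(als_ids)}).to_numpy()
    out.loc[idx, "surv_time"] = obs[order]
    out.loc[idx, "event"] = event[order].astype(float)
    truth = truth or TruthRecord()
    truth.planted_surv_genes = log_hrs
    return out, truth


def generate_gwas(
    genes: pd.DataFrame,
    target_genes: list[str],
    n_loci: int = 215,
    near_fraction: float = 0.5,
    max_offset_bp: int = 9_000,
    seed: int = 0,
) -> GwasLociSet:
    """Place susceptibility loci, a fraction of them near target genes.

    ``near_fraction`` of the loci fall within ``max_offset_bp`` of a randomly
    chosen target gene span (inside the span when the offset is 0); the rest
    are uniform over the chromosomes present in the gene table.
    """
    rng = np.random.default_rng(seed)
    if near_fraction > 0 and not target_genes:
        raise ValueError("near_fraction > 0 requires a non-empty target gene set")
    missing = set(target_genes) - set(genes["gene_id"])
    if missing:
        raise ValueError(f"target genes absent from gene table: {sorted(missing)[:5]}")

    gt = genes.set_index("gene_id")
    n_near = int(round(near_fraction * n_loci))
    rows = []
    if n_near:
        picks = rng.choice(target_genes, size=n_near, replace=True)
        for g in picks:
            start, end = int(gt.loc[g, "start"]), int(gt.loc[g, "end"])
            lo = max(1, start - max_offset_bp)
            hi = end + max_offset_bp
            rows.append({"chrom": gt.loc[g, "chrom"], "pos": int(rng.integers(lo, hi + 1))})
    chroms = genes["chrom"].unique()
    for _ in range(n_loci - n_near):
        rows.append({
            "chrom": rng.choice(chroms),
            "pos": int(rng.integers(1, CHROM_LENGTH_BP)),
        })
    return GwasLociSet(pd.DataFrame(rows))


def write_dataset(
    out_dir: str | Path,
    config: SimulationConfig,
    expr_c1: ExpressionMatrix,
    expr_c2: ExpressionMatrix,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    truth: TruthRecord,
    loci: GwasLociSet | None = None,
) -> None:
    """Write all simulator outputs as plain-text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_c1.to_tsv(out / "expr_c1.tsv", out / "detp_c1.tsv")
    expr_c2.to_tsv(out / "expr_c2.tsv", out / "detp_c2.tsv")
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    if loci is not None:
        loci.to_bed(out / "loci.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    config.to_yaml(out / "config.yaml")
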
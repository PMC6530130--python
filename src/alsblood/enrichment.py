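"""Rank-based enrichment, overlap tests, cell-type assignment, and
GWAS-locus proximity analysis with a gene-resampling null.

The rank enrichment statistic is the signed area between the cumulative
abundance curve of a gene set along a ranking and the diagonal, tested with
a two-sided Wilcoxon rank-sum comparison of set versus complement scores.
Set overlaps use Fisher's exact test.  Proximity of differentially expressed
genes to susceptibility loci is measured as point-to-interval base-pair
distance (0 inside a gene span), with an empirical p-value from resampling
random gene sets of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CELL_TYPES, CellTypeReference, GwasLociSet
from .diffexpr import bh_adjust


@dataclass
class RankEnrichmentResult:
    area_stat: float
    u_stat: float
    p: float
    curve: pd.DataFrame  # columns: rank_fraction, cumulative_fraction


def rank_enrichment_curve(ranking: pd.Series, gene_set: set[str]) -> RankEnrichmentResult:
    """Cumulative-abundance enrichment of ``gene_set`` along a score ranking.

    Genes are sorted by score descending (ties broken by gene id for
    determinism); the signed area statistic is the mean over ranks of
    (cumulative set fraction - diagonal), positive when the set concentrates
    at the top.
    """
    genes = ranking.index
    gene_set = set(gene_set) & set(genes)
    if not gene_set or len(gene_set) >= len(genes):
        raise ValueError("gene set must be a non-empty proper subset of the ranking")
    order = sorted(genes, key=lambda g: (-ranking[g], g))
    member = np.array([g in gene_set for g in order], dtype=float)
    n = len(order)
    cum = np.cumsum(member) / len(gene_set)
    diag = np.arange(1, n + 1) / n
    area = float(np.mean(cum - diag))
    in_scores = ranking[list(gene_set)].to_numpy()
    out_scores = ranking[[g for g in genes if g not in gene_set]].to_numpy()
    u, p = stats.mannwhitneyu(in_scores, out_scores, alternative="two-sided")
    curve = pd.DataFrame({"rank_fraction": diag, "cumulative_fraction": cum})
    return RankEnrichmentResult(area_stat=area, u_stat=float(u), p=float(p), curve=curve)


@dataclass
class OverlapTable:
    a: int  # in A and B
    b: int  # in A only
    c: int  # in B only
    d: int  # in neither
    odds_ratio: float
    p: float
    haldane: bool = False


def fisher_overlap(setA: set[str], setB: set[str], universe: set[str]) -> OverlapTable:
    """Two-sided Fisher's exact test of two gene-set memberships.

    The odds ratio uses the Haldane half-count correction when a cell is
    zero (flagged in the result).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(setA) & universe, set(setB) & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return OverlapTable(a, b, c, d, float(odds), float(p), haldane)


# ---------------------------------------------------------------------------
# cell-type assignment


def assign_cell_types(
    genes: list[str],
    reference: CellTypeReference,
    detect_min_frac: float = 0.10,
    detect_alpha: float = 0.05,
    floor_quantile: float = 0.10,
) -> pd.Series:
    """Assign each gene to the cell type where its reference expression peaks.

    A gene stays unassigned when no cell type has it detectable in at least
    ``detect_min_frac`` of that type's samples.  Detectability uses reference
    detection p-values (< ``detect_alpha``) when available, else expression
    above the compendium's ``floor_quantile`` expression floor.  Exact ties
    resolve to the first cell type in canonical order (with a warning).
    """
    cts = reference.cell_types
    means = reference.mean_profiles()[cts]
    if reference.detection_p is not None:
        detected = reference.detection_p < detect_alpha
    else:
        floor = np.quantile(reference.profiles.to_numpy(), floor_quantile)
        detected = reference.profiles > floor
    det_frac = pd.DataFrame(
        {ct: detected[reference.samples_of(ct)].mean(axis=1) for ct in cts})

    out = {}
    for g in genes:
        if g not in means.index:
            warnings.warn(f"gene {g} absent from reference; unassigned")
            out[g] = "unassigned"
            continue
        if not (det_frac.loc[g] >= detect_min_frac).any():
            out[g] = "unassigned"
            continue
        row = means.loc[g]
        top = row.max()
        winners = [ct for ct in cts if row[ct] == top]
        if len(winners) > 1:
            warnings.warn(f"gene {g}: tie among {winners}; first canonical type kept")
        out[g] = winners[0]
    return pd.Series(out, name="cell_type")


def assignment_enrichment(
    assignment: pd.Series, deg_set: set[str], universe: set[str]
) -> pd.DataFrame:
    """Per-cell-type Fisher test of assignment x DEG membership, BH across types."""
    deg_set = set(deg_set) & set(universe)
    rows = []
    types = [ct for ct in assignment.unique() if ct != "unassigned"]
    types = [ct for ct in CELL_TYPES if ct in types] + [t for t in types if t not in CELL_TYPES]
    for ct in types:
        assigned = set(assignment.index[assignment == ct]) & set(universe)
        tab = fisher_overlap(assigned, deg_set, universe)
        rows.append({"cell_type": ct, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                     "odds_ratio": tab.odds_ratio, "p": tab.p})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.set_index("cell_type", drop=False)


# ---------------------------------------------------------------------------
# GWAS proximity


def nearest_locus_distances(genes: pd.DataFrame, loci: GwasLociSet) -> pd.Series:
    """Base-pair distance from each gene span to its nearest locus.

    Point-to-interval on 1-based inclusive spans: 0 when the locus falls
    inside the gene.  Genes on chromosomes without loci get +inf.
    """
    if loci.n_loci == 0:
        raise ValueError("empty locus set")
    out = np.full(len(genes), np.inf)
    by_chrom = {c: np.sort(sub["pos"].to_numpy())
                for c, sub in loci.loci.groupby("chrom")}
    for chrom, sub in genes.groupby("chrom"):
        pos = by_chrom.get(chrom)
        if pos is None:
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        # candidate loci: nearest at or below start, nearest at or above end,
        # plus anything inside the span
        i_lo = np.clip(np.searchsorted(pos, start) - 1, 0, len(pos) - 1)
        i_hi = np.clip(np.searchsorted(pos, end), 0, len(pos) - 1)
        d = np.full(len(sub), np.inf)
        for cand in (i_lo, i_hi, np.clip(i_lo + 1, 0, len(pos) - 1)):
            p = pos[cand]
            dist = np.maximum.reduce([start - p, p - end, np.zeros(len(sub))])
            d = np.minimum(d, dist)
        out[genes.index.get_indexer(sub.index)] = d
    return pd.Series(out, index=genes["gene_id"].to_numpy(), name="distance_bp")


@dataclass
class ProximityResult:
    distances: pd.Series
    thresholds: list[int] = field(default_factory=list)
    table: pd.DataFrame | None = None        # per-threshold fractions + Fisher p
    observed_mean: float | None = None
    null_means: np.ndarray | None = None
    empirical_p: float | None = None


def gwas_proximity_overlap(
    ranked_degs: list[str],
    genes: pd.DataFrame,
    loci: GwasLociSet,
    thresholds: list[int],
    universe: list[str] | None = None,
) -> ProximityResult:
    """Per-threshold overlap of a top-ranked gene set with locus-proximal genes.

    For each distance threshold, the fraction of the top set versus remaining
    universe genes lying within that distance of a locus is compared by a
    two-sided Fisher test.
    """
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    dist = nearest_locus_distances(genes, loci)
    if universe is None:
        universe = list(dist.index)
    top = [g for g in ranked_degs if g in dist.index]
    rest = [g for g in universe if g not in set(top) and g in dist.index]
    rows = []
    for thr in thresholds:
        near = dist.index[dist <= thr]
        near_set = set(near)
        a = sum(g in near_set for g in top)
        c = sum(g in near_set for g in rest)
        _, p = stats.fisher_exact(
            [[a, len(top) - a], [c, len(rest) - c]], alternative="two-sided")
        rows.append({
            "threshold_bp": thr,
            "deg_frac": a / len(top) if top else np.nan,
            "background_frac": c / len(rest) if rest else np.nan,
            "deg_near": a, "background_near": c, "p": float(p),
        })
    return ProximityResult(distances=dist, thresholds=list(thresholds),
                           table=pd.DataFrame(rows))


def gwas_distance_null(
    top_set: list[str],
    universe: list[str],
    genes: pd.DataFrame,
    loci: GwasLociSet,
    n_trials: int = 10_000,
    seed: int = 0,
    distances: pd.Series | None = None,
) -> ProximityResult:
    """Resampling null for the mean nearest-locus distance of a gene set.

    The observed mean distance over ``top_set`` is compared with means from
    ``n_trials`` equally sized uniform draws (without replacement) from the
    universe; the empirical p-value uses the add-one rule
    ``(1 + #{null <= observed}) / (n_trials + 1)`` and can never be zero.
    """
    if n_trials < 100:
        warnings.warn("fewer than 100 trials gives a coarse empirical p")
    if len(top_set) > len(universe):
        raise ValueError("top set larger than universe")
    if distances is None:
        distances = nearest_locus_distances(genes, loci)
    # genes on chromosomes without any locus have no defined distance;
    # they drop out of both the observed set and the resampling pool
    finite = set(distances.index[np.isfinite(distances)])
    top_set = [g for g in top_set if g in finite]
    universe = [g for g in universe if g in finite]
    if not top_set:
        raise ValueError("no top-set gene has a finite nearest-locus distance")
    d_universe = distances.loc[list(universe)].to_numpy()
    observed = float(distances.loc[list(top_set)].mean())
    rng = np.random.default_rng(seed)
    k = len(top_set)
    null = np.empty(n_trials)
    for t in range(n_trials):
        idx = rng.choice(len(d_universe), size=k, replace=False)
        null[t] = d_universe[idx].mean()
    emp_p = (1 + int(np.sum(null <= observed))) / (n_trials + 1)
    return ProximityResult(distances=distances, observed_mean=observed,
                           null_means=null, empirical_p=float(emp_p))


# ---------------------------------------------------------------------------
# external signature correspondence


def signature_correspondence_screen(
    signatures: dict[str, pd.Series],
    inc_top: list[str],
    dec_top: list[str],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Rank external signatures by how they mirror the case expression shift.

    Each signature maps genes to signed log10 p-values (positive = increased).
    Per signature, the medians within the top-increased and top-decreased
    gene sets are compared by a two-sided rank-sum test; signatures covering
    less than ``min_coverage`` of either set are skipped with a warning.
    Matching-direction signatures (inc median > dec median) rank first, by p.
    """
    if set(inc_top) & set(dec_top):
        raise ValueError("inc_top and dec_top must be disjoint")
    rows = []
    for sig_id, values in signatures.items():
        inc_vals = values.reindex(inc_top).dropna()
        dec_vals = values.reindex(dec_top).dropna()
        cov_inc = len(inc_vals) / len(inc_top)
        cov_dec = len(dec_vals) / len(dec_top)
        if cov_inc < min_coverage or cov_dec < min_coverage:
            warnings.warn(
                f"signature {sig_id}: coverage {cov_inc:.2f}/{cov_dec:.2f} "
                "below threshold; skipped")
            continue
        _, p = stats.mannwhitneyu(inc_vals, dec_vals, alternative="two-sided")
        rows.append({
            "signature_id": sig_id,
            "inc_median": float(inc_vals.median()),
            "dec_median": float(dec_vals.median()),
            "coverage_inc": cov_inc, "coverage_dec": cov_dec,
            "p": float(p),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["direction_match"] = table["inc_median"] > table["dec_median"]
        table = table.sort_values(["direction_match", "p"],
                                  ascending=[False, True]).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    return table
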
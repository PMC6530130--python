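"""In-silico immune cell-type scoring from whole-blood expression.

Cell-type signatures are derived from a purified reference compendium: for
each cell type, a two-group moderated-t comparison of that type against all
others selects the 150 elevated genes with lowest p-values, which are then
re-sorted by fold change and truncated to the 100 highest-FC genes.  Rank r
receives weight ``sqrt(101 - r) / 10`` (preliminary weights 100..1, square
root, scaled by the maximum), and a sample's signature score is the weighted
mean of its Z-scored expression over the signature genes.  Myeloid and
lymphoid composite scores (unweighted means of the constituent cell scores)
define patient subgroups via symmetric +/-0.05 thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellTypeReference, ExpressionMatrix
from .diffexpr import moderated_ttest

MYELOID_TYPES = ["DC", "MP", "MC", "NP", "PL", "RBC", "ES"]
LYMPHOID_TYPES = ["CD8", "CD4", "GDT", "NK", "B"]


def signature_weights(n: int) -> np.ndarray:
    """Square-root rank weights scaled to (0, 1]; rank 1 gets weight 1.

    For the default 100-gene scheme this is exactly ``sqrt(101 - r) / 10``.
    """
    r = np.arange(1, n + 1)
    prelim = np.sqrt(n + 1 - r)
    return prelim / prelim.max()


@dataclass
class SignatureDefinition:
    """Ranked, weighted signature gene list (rank 1 = most specific)."""

    label: str
    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must align")
        if np.any(np.diff(self.weights) >= 0):
            raise ValueError("weights must be strictly decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.label,
            "rank": np.arange(1, len(self.genes) + 1),
            "gene": self.genes,
            "weight": self.weights,
        })


def select_signature_genes(
    reference: CellTypeReference,
    target: str,
    n_p: int = 150,
    n_fc: int = 100,
) -> SignatureDefinition:
    """Two-stage signature selection: lowest-p elevated genes, then highest FC.

    A moderated-t comparison of the target cell type against the pooled other
    types ranks elevated genes (FC > 1) by p-value; the ``n_p`` best are
    re-sorted by fold change descending and truncated to ``n_fc`` genes,
    whose FC order defines signature ranks and weights.
    """
    if target not in set(reference.sample_types):
        raise ValueError(f"cell type {target} not in reference")
    labels = reference.sample_types.map(lambda t: "target" if t == target else "rest")
    expr = ExpressionMatrix(reference.profiles)
    de, _ = moderated_ttest(expr, labels, case="target", control="rest")
    # strictly elevated, with an epsilon floor so numerically identical
    # profiles (log2fc at rounding level) cannot qualify
    elevated = de[de["log2fc"] > 1e-9]
    if len(elevated) < n_fc:
        raise ValueError(
            f"only {len(elevated)} elevated genes for {target}; need {n_fc}")
    top_p = elevated.nsmallest(n_p, "p")
    chosen = top_p.reset_index(drop=True).sort_values(
        ["log2fc", "gene_id"], ascending=[False, True]).head(n_fc)
    genes = chosen["gene_id"].tolist()
    return SignatureDefinition(target, genes, signature_weights(len(genes)))


def compute_signature_scores(
    expr_z: ExpressionMatrix,
    signatures: list[SignatureDefinition],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-sample weighted-mean scores of Z-scored expression (samples x labels).

    Missing signature genes are dropped with weights renormalized over the
    present genes; coverage below ``min_coverage`` triggers a warning and
    zero coverage is an error.
    """
    out = {}
    for sig in signatures:
        present = [g for g in sig.genes if g in expr_z.gene_ids]
        if not present:
            raise ValueError(f"signature {sig.label}: no genes present in matrix")
        coverage = len(present) / len(sig.genes)
        if coverage < min_coverage:
            warnings.warn(
                f"signature {sig.label}: coverage {coverage:.2f} below "
                f"{min_coverage}; scoring on present genes")
        w = np.array([sig.weights[sig.genes.index(g)] for g in present])
        Z = expr_z.values.loc[present].to_numpy()
        out[sig.label] = (w @ Z) / w.sum()
    return pd.DataFrame(out, index=expr_z.sample_ids)


def composite_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Myeloid and lymphoid composites: unweighted means of constituent scores."""
    for ct in MYELOID_TYPES + LYMPHOID_TYPES:
        if ct not in scores.columns:
            raise ValueError(f"missing constituent score: {ct}")
    return pd.DataFrame({
        "myeloid": scores[MYELOID_TYPES].mean(axis=1),
        "lymphoid": scores[LYMPHOID_TYPES].mean(axis=1),
    })


def assign_subgroups(
    myeloid: pd.Series, lymphoid: pd.Series, t: float = 0.05
) -> pd.DataFrame:
    """Threshold rule for patient subgroups.

    myeloid group: myeloid score > t and lymphoid score < -t; lymphoid group:
    myeloid score < -t and lymphoid score > t; everything else unassigned.
    """
    if not (np.isfinite(myeloid).all() and np.isfinite(lymphoid).all()):
        raise ValueError("scores must be finite")
    label = pd.Series("unassigned", index=myeloid.index, dtype=object)
    label[(myeloid > t) & (lymphoid < -t)] = "myeloid"
    label[(myeloid < -t) & (lymphoid > t)] = "lymphoid"
    return pd.DataFrame({"subgroup": label, "myeloid_score": myeloid,
                         "lymphoid_score": lymphoid})


def polarization_signatures(
    m_reference: CellTypeReference,
    m1_label: str = "M1",
    m2_label: str = "M2",
    n_p: int = 150,
    n_fc: int = 100,
) -> tuple[SignatureDefinition, SignatureDefinition]:
    """M1 and M2 macrophage polarization signatures.

    The M1 signature comes from comparing M1 samples against the pooled M2
    and non-polarized samples (and mirrored for M2), using the same
    selection scheme as the cell-type signatures.
    """
    present = set(m_reference.sample_types)
    for lab in (m1_label, m2_label):
        if lab not in present:
            raise ValueError(f"reference missing class {lab}")
    if len(present) < 3:
        raise ValueError("reference must include a non-polarized class")
    sig_m1 = select_signature_genes(m_reference, m1_label, n_p=n_p, n_fc=n_fc)
    sig_m2 = select_signature_genes(m_reference, m2_label, n_p=n_p, n_fc=n_fc)
    return sig_m1, sig_m2


def signatures_to_tsv(signatures: list[SignatureDefinition], path) -> None:
    pd.concat([s.to_frame() for s in signatures]).to_csv(path, sep="\t", index=False)


def signatures_from_tsv(path) -> list[SignatureDefinition]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for label, sub in df.groupby("label", sort=False):
        sub = sub.sort_values("rank")
        out.append(SignatureDefinition(label, sub["gene"].tolist(),
                                       sub["weight"].to_numpy()))
    return out
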
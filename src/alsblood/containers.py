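"""Core data containers shared across the pipeline.

The pipeline operates on a small set of tabular objects: a genes x samples
log2 expression matrix with optional bead-array detection p-values, a sample
annotation table, a gene coordinate table, a purified cell-type reference
compendium, and a set of GWAS susceptibility loci.  Tables are plain pandas
DataFrames with documented column contracts; the expression matrix and the
reference get thin dataclass wrappers because they pair several aligned
grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Canonical whole-blood cell types, in the fixed order used for tie-breaks.
CELL_TYPES = ["NP", "MC", "DC", "MP", "PL", "RBC", "ES", "CD4", "CD8", "GDT", "B", "NK"]

#: Columns required in a sample annotation table.
SAMPLE_COLUMNS = [
    "sample_id", "cohort", "platform", "batch", "group", "sex", "age",
    "onset_site", "surv_time", "event",
]

#: Columns required in a gene annotation table (1-based inclusive coordinates).
GENE_COLUMNS = ["gene_id", "symbol", "coding", "chrom", "start", "end", "refseq_prefix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid (log2 unless a step documents otherwise).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    detection_p
        Optional DataFrame of the same shape holding per-(gene, sample)
        detection p-values in [0, 1].
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape must match values")
            p = self.detection_p.to_numpy(dtype=float)
            if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
                raise ValueError("detection_p must lie in [0, 1]")
            self.detection_p = self.detection_p.loc[self.values.index, self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            None if self.detection_p is None else self.detection_p.copy(),
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes],
            None if self.detection_p is None else self.detection_p.loc[genes],
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples],
            None if self.detection_p is None else self.detection_p[samples],
        )

    def to_tsv(self, values_path: str | Path, detp_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        if detp_path is not None and self.detection_p is not None:
            self.detection_p.to_csv(detp_path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, values_path: str | Path, detp_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
        detp = None
        if detp_path is not None:
            detp = pd.read_csv(detp_path, sep="\t", index_col="gene_id")
        return cls(values, detp)


@dataclass
class CellTypeReference:
    """Purified cell-type expression compendium (log2, genes x reference samples).

    ``sample_types`` maps each reference sample to its cell type; every cell
    type must contribute at least two samples.
    """

    profiles: pd.DataFrame
    sample_types: pd.Series
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_types = self.sample_types.loc[self.profiles.columns]
        counts = self.sample_types.value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"cell types with fewer than 2 samples: {bad}")

    @property
    def cell_types(self) -> list[str]:
        seen = dict.fromkeys(self.sample_types)
        return [c for c in CELL_TYPES if c in seen] + [c for c in seen if c not in CELL_TYPES]

    @property
    def samples_per_type(self) -> pd.Series:
        return self.sample_types.value_counts()

    def samples_of(self, cell_type: str) -> list[str]:
        return self.sample_types.index[self.sample_types == cell_type].tolist()

    def mean_profiles(self) -> pd.DataFrame:
        """Per-cell-type mean log2 profile (genes x cell types)."""
        out = {}
        for ct in self.cell_types:
            out[ct] = self.profiles[self.samples_of(ct)].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class GwasLociSet:
    """Susceptibility loci as (chrom, 1-based position) points."""

    loci: pd.DataFrame  # columns: chrom, pos

    def __post_init__(self) -> None:
        if (self.loci["pos"] < 1).any():
            raise ValueError("locus positions must be >= 1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_bed(self, path: str | Path) -> None:
        bed = pd.DataFrame({
            "chrom": self.loci["chrom"],
            "start": self.loci["pos"] - 1,   # BED is 0-based half-open
            "end": self.loci["pos"],
        })
        bed.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GwasLociSet":
        bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                          usecols=[0, 1, 2])
        return cls(pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"] + 1}))


@dataclass
class TruthRecord:
    """Ground truth emitted by the simulator for parameter-recovery testing."""

    planted_degs: dict[str, float] = field(default_factory=dict)
    planted_props: pd.DataFrame | None = None          # samples x cell types
    planted_surv_genes: dict[str, float] = field(default_factory=dict)
    loci_target_genes: list[str] = field(default_factory=list)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    flipped_samples: list[str] = field(default_factory=list)
    sex_genes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "planted_degs": self.planted_degs,
            "planted_surv_genes": self.planted_surv_genes,
            "loci_target_genes": self.loci_target_genes,
            "marker_genes": self.marker_genes,
            "flipped_samples": self.flipped_samples,
            "sex_genes": self.sex_genes,
        }
        if self.planted_props is not None:
            d["planted_props"] = {
                s: self.planted_props.loc[s].to_dict() for s in self.planted_props.index
            }
        return d


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Check the sample-table column contract and cross-field invariants."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    mim = samples[samples["group"] == "MIM"]
    if len(mim) and not (mim["cohort"] == "C2").all():
        raise ValueError("MIM samples may occur only in cohort C2")
    als = samples["group"] == "ALS"
    has_surv = samples["surv_time"].notna()
    if (has_surv & ~als).any():
        raise ValueError("surv_time present for a non-ALS sample")


def validate_gene_table(genes: pd.DataFrame) -> None:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must be <= end (1-based inclusive)")


def genes_to_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Export 1-based inclusive gene spans as 0-based half-open BED."""
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"] - 1,
        "end": genes["end"],
        "name": genes["gene_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
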
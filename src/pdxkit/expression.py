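"""Expression matrix I/O and normalisation.

Matrices are stored gene-major: rows are genes, columns are samples,
tab-separated with a header row of sample ids and the gene id in the first
column.  RPKM is computed from raw counts using an externally supplied
library size per sample (total aligned reads, not the column sum, which
under-counts under intersection-strict read assignment) and the maximal
mature transcript length of each gene, supplied as a precomputed
annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionError",
    "ExpressionMatrix",
    "read_gene_annotation",
    "read_library_sizes",
    "compute_rpkm",
    "intersect_on_coding_genes",
]


class ExpressionError(ValueError):
    """Raised on malformed expression data or annotation mismatches."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    unit
        Either ``"counts"`` or ``"rpkm"``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpkm"):
            raise ExpressionError(f"unknown expression unit {self.unit!r}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ExpressionError(f"duplicated gene id {dup!r}")
        if not self.data.columns.is_unique:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ExpressionError(f"duplicated sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ExpressionError("expression values must be non-negative")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression as a gene-indexed Series."""
        return self.data[sample_id]

    @classmethod
    def read_tsv(cls, path, unit: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, unit=unit)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, max_transcript_length, is_coding).

    Returns a DataFrame indexed by gene id.  Transcript lengths must be
    positive integers; gene ids must be unique.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "max_transcript_length", "is_coding"}
    missing = required - set(ann.columns)
    if missing:
        raise ExpressionError(f"annotation file lacks columns: {sorted(missing)}")
    ann = ann.set_index("gene_id")
    if not ann.index.is_unique:
        dup = ann.index[ann.index.duplicated()][0]
        raise ExpressionError(f"duplicated gene id {dup!r} in annotation")
    if (ann["max_transcript_length"] < 1).any():
        bad = ann.index[ann["max_transcript_length"] < 1][0]
        raise ExpressionError(f"non-positive transcript length for gene {bad!r}")
    ann["is_coding"] = ann["is_coding"].astype(bool)
    return ann


def read_library_sizes(path) -> pd.Series:
    """Read a two-column table (sample_id, total_reads) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "total_reads"} <= set(df.columns):
        raise ExpressionError("library-size file needs columns sample_id, total_reads")
    return df.set_index("sample_id")["total_reads"]


def compute_rpkm(
    counts: ExpressionMatrix,
    genes: pd.DataFrame,
    library_sizes: pd.Series,
) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm(g, s) = counts(g, s) / (library_sizes[s] / 1e6)
    / (max_transcript_length[g] / 1e3)`` using the maximal mature
    transcript length of each gene.
    """
    if counts.unit != "counts":
        raise ExpressionError("compute_rpkm expects a counts matrix")
    missing_genes = counts.data.index.difference(genes.index)
    if len(missing_genes):
        raise ExpressionError(
            f"gene {missing_genes[0]!r} has no annotation "
            f"({len(missing_genes)} genes missing in total)"
        )
    missing_samples = counts.data.columns.difference(library_sizes.index)
    if len(missing_samples):
        raise ExpressionError(f"no library size for sample {missing_samples[0]!r}")
    libs = library_sizes.reindex(counts.data.columns).astype(float)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0][0]
        raise ExpressionError(f"non-positive library size for sample {bad!r}")
    lengths = genes["max_transcript_length"].reindex(counts.data.index).astype(float)
    rpkm = counts.data.div(libs / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return ExpressionMatrix(rpkm, unit="rpkm")


def intersect_on_coding_genes(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    genes: pd.DataFrame,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the coding genes they share.

    The output gene order follows the first matrix.  Correlating fewer than
    two genes is meaningless, so fewer than two shared coding genes is an
    error.
    """
    coding = set(genes.index[genes["is_coding"]])
    shared = [g for g in a.gene_ids if g in coding and g in b.data.index]
    if len(shared) < 2:
        raise ExpressionError(
            f"only {len(shared)} shared coding gene(s); need at least 2"
        )
    return (
        ExpressionMatrix(a.data.loc[shared], unit=a.unit),
        ExpressionMatrix(b.data.loc[shared], unit=b.unit),
    )
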
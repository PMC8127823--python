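"""Expression-matrix I/O and transforms.

Tissue expression tables (FPKM) for the duplicated species (Atlantic salmon)
and the diploid outgroup proxy (Northern pike) are the substrate of every
homeolog-fate analysis in this package.  This module reads and writes the
tables, applies the expressed filter (max tissue FPKM strictly above a
threshold, 1.0 by default), the ``log2(FPKM + 1)`` transform used for all
correlation work, and aligns the two species onto their shared tissue panel
(13 tissues in the salmon/pike design; salmon has two extra tissues that
take part in clustering but not in cross-species correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TissueMap",
    "read_expression_table",
    "write_expression_table",
    "filter_expressed",
    "log2_transform",
    "align_common_tissues",
]


class ExpressionError(ValueError):
    """Raised for malformed expression tables or misuse of scale contracts."""


@dataclass
class ExpressionMatrix:
    """Genes x tissues expression values for one species.

    ``values`` is a pandas DataFrame indexed by gene id with tissue-name
    columns.  ``log_scale`` records whether values are raw FPKM or
    log2(FPKM+1); downstream operations enforce the scale they need.
    """

    values: pd.DataFrame
    species: str = ""
    log_scale: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene ids: {dupes}")
        if v.columns.has_duplicates:
            raise ExpressionError("duplicate tissue names")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ExpressionError("missing values are not supported; encode absence as 0 FPKM")
        if (arr < 0).any():
            raise ExpressionError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])


@dataclass
class TissueMap:
    """Ordered pairing of salmon tissue names with pike tissue names."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ExpressionError("tissue map must be injective in both directions")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, tissues) -> "TissueMap":
        return cls([(t, t) for t in tissues])

    @classmethod
    def read(cls, path) -> "TissueMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 2:
            raise ExpressionError("tissue map TSV must have exactly two columns")
        return cls(list(df.itertuples(index=False, name=None)))

    def write(self, path) -> None:
        pd.DataFrame(self.pairs).to_csv(path, sep="\t", header=False, index=False)


def read_expression_table(path, species: str = "") -> ExpressionMatrix:
    """Read a TSV with a tissue-name header row and one gene per row.

    The first column holds gene ids.  Values are raw FPKM; malformed numeric
    cells, duplicated gene ids and negative values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ExpressionError(f"non-numeric expression cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, species=species, log_scale=False)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    # fixed float format keeps outputs byte-identical across runs
    out.to_csv(path, sep="\t", float_format="%.6f")


def filter_expressed(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum tissue FPKM is strictly above ``threshold``.

    Operates on raw FPKM only.  A gene at exactly the threshold in every
    tissue is dropped ("above" is a strict inequality).
    """
    if m.log_scale:
        raise ExpressionError("filter_expressed requires raw FPKM values, not log scale")
    keep = m.values.max(axis=1) > threshold
    return replace(m, values=m.values.loc[keep])


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a matrix of log2(FPKM + 1) values; refuses to transform twice."""
    if m.log_scale:
        raise ExpressionError("matrix is already on log2(FPKM+1) scale")
    return replace(m, values=np.log2(m.values + 1.0), log_scale=True)


def align_common_tissues(
    salmon: ExpressionMatrix, pike: ExpressionMatrix, tissue_map: TissueMap
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the mapped common tissues, in map order.

    Salmon-only tissues are dropped from the paired view only; the inputs
    are untouched.  Unmapped tissue names raise with the offending name.
    """
    s_cols = [a for a, _ in tissue_map.pairs]
    p_cols = [b for _, b in tissue_map.pairs]
    for name in s_cols:
        if name not in salmon.values.columns:
            raise ExpressionError(f"tissue {name!r} not present in {salmon.species or 'salmon'} matrix")
    for name in p_cols:
        if name not in pike.values.columns:
            raise ExpressionError(f"tissue {name!r} not present in {pike.species or 'pike'} matrix")
    return (
        replace(salmon, values=salmon.values[s_cols]),
        replace(pike, values=pike.values[p_cols]),
    )
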
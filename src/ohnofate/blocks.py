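"""Homeolog-block similarity tracks and TE divergence landscapes.

After a whole-genome duplication the two copies of each chromosomal region
(homeolog blocks) diverge in sequence; regions that rediploidized late —
or still pair tetrasomically — stay more similar.  This module turns local
alignment HSPs (high-scoring segment pairs) between duplicated regions
into per-window (1 Mb by default) mean-identity tracks with the three
similarity categories used for the salmon genome (high >95%, elevated
90-95%, low ~87%), and computes pairwise per-cent-identity distributions
within transposable-element families from multiple alignments — a proxy
for the timing of TE expansion bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "HSP",
    "WindowSimilarityTrack",
    "read_hsp_table",
    "windowed_identity",
    "similarity_category",
    "pairwise_identity",
    "read_alignment_fasta",
    "identity_histogram",
]


@dataclass(frozen=True)
class HSP:
    """A local alignment block between two duplicated regions.

    Coordinates are 0-based half-open; identity is a percentage in [0, 100].
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError(f"HSP with non-positive length: {self}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"HSP identity outside [0, 100]: {self.identity}")


@dataclass
class WindowSimilarityTrack:
    """Per-window mean homeolog identity along one chromosome."""

    chrom: str
    window: int
    table: pd.DataFrame  # columns: start, end, identity (nan = missing), category

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "chrom", self.chrom)
        out.to_csv(path, sep="\t", index=False)


def read_hsp_table(path) -> list[HSP]:
    """Read a 7-column HSP TSV (chromA, startA, endA, chromB, startB, endB, identity)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "identity"],
    )
    return [HSP(**row) for row in df.to_dict(orient="records")]


def similarity_category(identity: float) -> str:
    """Similarity class of a window: high (>95), elevated (90-95), low (<90)."""
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity outside [0, 100]: {identity}")
    if identity > 95.0:
        return "high"
    if identity >= 90.0:
        return "elevated"
    return "low"


def windowed_identity(
    hsps: list[HSP], window: int = 1_000_000, chrom_length: int | None = None
) -> WindowSimilarityTrack:
    """Length-weighted mean HSP identity in fixed windows along one chromosome.

    Windows tile [0, chrom_length) as [k*w, (k+1)*w) using the A-side
    coordinates; each HSP contributes its identity weighted by the length
    of its overlap with the window.  Windows with no overlapping HSP are
    missing (nan identity, category 'none').
    """
    if not hsps:
        raise ValueError("need at least one HSP")
    chroms = {h.chrom_a for h in hsps}
    if len(chroms) != 1:
        raise ValueError(f"HSPs span several A-side chromosomes: {sorted(chroms)}")
    (chrom,) = chroms
    end = chrom_length if chrom_length is not None else max(h.end_a for h in hsps)
    n_windows = int(np.ceil(end / window))
    weight = np.zeros(n_windows)
    weighted_id = np.zeros(n_windows)
    for h in hsps:
        first = h.start_a // window
        last = (h.end_a - 1) // window
        for w in range(first, min(last + 1, n_windows)):
            lo = max(h.start_a, w * window)
            hi = min(h.end_a, (w + 1) * window)
            if hi > lo:
                weight[w] += hi - lo
                weighted_id[w] += (hi - lo) * h.identity
    with np.errstate(invalid="ignore"):
        mean_id = np.where(weight > 0, weighted_id / np.where(weight > 0, weight, 1), np.nan)
    rows = []
    for w in range(n_windows):
        ident = mean_id[w]
        cat = "none" if np.isnan(ident) else similarity_category(float(ident))
        rows.append((w * window, (w + 1) * window, ident, cat))
    return WindowSimilarityTrack(
        chrom=chrom,
        window=window,
        table=pd.DataFrame(rows, columns=["start", "end", "identity", "category"]),
    )


def read_alignment_fasta(path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA; returns (names, equal-length sequences)."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal length")
    return names, seqs


def pairwise_identity(seqs: list[str]) -> np.ndarray:
    """Per-cent identity matrix between aligned sequences.

    identity(i, j) = matches / comparable columns * 100, where a column is
    comparable for the pair iff neither sequence has a gap ('-') or an 'N'
    there (exclusion is pairwise, not list-wise).  Pairs with zero
    comparable columns are nan.  Diagonal is 100.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in seqs])
    ok = (arr != "-") & (arr != "N")
    n = len(seqs)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            comparable = int(both.sum())
            if comparable == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            matches = int((arr[i][both] == arr[j][both]).sum())
            out[i, j] = out[j, i] = 100.0 * matches / comparable
    return out


def identity_histogram(values, bin_width: float = 1.0) -> pd.DataFrame:
    """Fixed-width histogram of per-cent identities over [0, 100].

    Bins are [lo, lo + w) with the last bin closed at 100, so the counts
    sum to the number of input values.
    """
    vals = np.asarray(list(values), dtype=float)
    if len(vals) and (vals.min() < 0 or vals.max() > 100):
        raise ValueError("identities must lie in [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
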
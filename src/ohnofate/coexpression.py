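"""Co-expression clustering of gene profiles and homeolog-pair divergence.

Profiles (log2(FPKM+1)) are clustered with Ward linkage on a Pearson
correlation distance (d = 1 - r).  A homeolog pair counts as
regulation-diverged when its two members fall in different co-expression
clusters, and enrichment of divergence between specific cluster pairs is
assessed by a partner-permutation randomization test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "HomeologPairSet",
    "correlation_distance",
    "ward_clusters",
    "pair_divergence",
    "cluster_pair_enrichment",
]


@dataclass
class ClusterAssignment:
    """Gene -> cluster label (1..k) plus the Ward merge history."""

    labels: dict[str, int]
    k: int
    linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if present and (min(present) < 1 or max(present) > self.k):
            raise ValueError("cluster labels must lie in 1..k")
        if len(present) != self.k:
            raise ValueError("every cluster label 1..k must be non-empty")

    def __getitem__(self, gene: str) -> int:
        return self.labels[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.labels), "cluster": list(self.labels.values())}
        )


@dataclass
class HomeologPairSet:
    """Unordered homeolog (gene duplicate) pairs; a gene appears in one pair at most."""

    pairs: list[tuple[str, str]]
    block_ids: list[str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair ({a!r}, {b!r}) duplicates a gene with itself")
            if a in seen or b in seen:
                raise ValueError(f"gene appears in more than one pair: ({a}, {b})")
            seen.update((a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def read(cls, path) -> "HomeologPairSet":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        return cls(list(df.iloc[:, :2].itertuples(index=False, name=None)))

    def write(self, path) -> None:
        pd.DataFrame(self.pairs).to_csv(path, sep="\t", header=False, index=False)


def correlation_distance(m: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation distance d(i, j) = 1 - r(i, j) between gene profiles.

    Requires log-scale profiles over at least 3 tissues.  Genes with zero
    variance have no defined correlation; they are excluded with a warning
    (the returned matrix simply omits them).  Anticorrelation maps to d = 2:
    the distance deliberately uses r, not |r|, because anticorrelated
    profiles are regulatorily divergent.
    """
    if not m.log_scale:
        raise ValueError("correlation_distance expects log2(FPKM+1) values")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 tissues for a meaningful correlation")
    var = m.values.var(axis=1)
    flat = var[var == 0.0].index.tolist()
    vals = m.values
    if flat:
        warnings.warn(
            f"excluding {len(flat)} zero-variance gene(s) from clustering", stacklevel=2
        )
        vals = vals.drop(index=flat)
    corr = np.corrcoef(vals.to_numpy(dtype=float))
    corr = np.atleast_2d(corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=vals.index, columns=vals.index)


def ward_clusters(d: pd.DataFrame, k: int) -> ClusterAssignment:
    """Cut a Ward-linkage agglomeration of the distance matrix into k clusters.

    Mirrors R's ``hclust(method="ward")`` on a precomputed correlation
    distance.  Deterministic for a given input order; scipy breaks merge
    ties by lowest index.
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if n == 1:
        return ClusterAssignment(labels={d.index[0]: 1}, k=1, linkage=None)
    condensed = squareform(d.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel so clusters are numbered 1..k in order of first appearance
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gene, raw in zip(d.index, flat):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        labels[gene] = relabel[raw]
    return ClusterAssignment(labels=labels, k=len(relabel), linkage=Z)


def pair_divergence(
    c: ClusterAssignment, pairs: HomeologPairSet
) -> tuple[pd.DataFrame, float, int]:
    """Flag each homeolog pair as diverged (different clusters) or not.

    Returns (per-pair table, diverged fraction, n_skipped).  Pairs with an
    unclustered member are skipped with a warning and counted.
    """
    rows = []
    skipped = 0
    for a, b in pairs.pairs:
        if a not in c or b not in c:
            skipped += 1
            continue
        rows.append((a, b, c[a], c[b], c[a] != c[b]))
    if skipped:
        warnings.warn(f"skipped {skipped} pair(s) with unclustered genes", stacklevel=2)
    df = pd.DataFrame(rows, columns=["geneA", "geneB", "clusterA", "clusterB", "diverged"])
    frac = float(df["diverged"].mean()) if len(df) else float("nan")
    return df, frac, skipped


def cluster_pair_enrichment(
    c: ClusterAssignment,
    pairs: HomeologPairSet,
    n_rand: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Randomization test for enrichment of homeolog pairs between cluster pairs.

    The null shuffles the second member across pairs (cluster assignments
    fixed), preserving marginal cluster occupancy and the pair count.  For
    each unordered cluster pair (i, j) the empirical p uses an add-one
    pseudo-count: p = (1 + #{permutations with count >= observed}) / (1 + n_rand),
    so p lies in (0, 1].
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    df, _, _ = pair_divergence(c, pairs)
    la = df["clusterA"].to_numpy(dtype=np.int64)
    lb = df["clusterB"].to_numpy(dtype=np.int64)
    k = c.k
    ncell = k * (k + 1) // 2

    def pair_key(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        lo = np.minimum(x, y) - 1
        hi = np.maximum(x, y) - 1
        # index into the upper triangle (including diagonal) of a k x k grid
        return lo * k - lo * (lo - 1) // 2 + (hi - lo)

    observed = np.bincount(pair_key(la, lb), minlength=ncell)
    rng = np.random.default_rng(seed)
    ge = np.zeros(ncell, dtype=np.int64)
    for _ in range(n_rand):
        perm = rng.permutation(lb)
        counts = np.bincount(pair_key(la, perm), minlength=ncell)
        ge += counts >= observed
    pvals = (1.0 + ge) / (1.0 + n_rand)

    rows = []
    idx = 0
    for i in range(1, k + 1):
        for j in range(i, k + 1):
            rows.append((i, j, int(observed[idx]), float(pvals[idx])))
            idx += 1
    return pd.DataFrame(rows, columns=["cluster_i", "cluster_j", "observed", "p_value"])
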
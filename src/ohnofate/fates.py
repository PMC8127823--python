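"""Homeolog-pair fate classification against a diploid outgroup proxy.

An ortholog triplet is two salmonid WGD duplicates (Ss4R homeologs) plus
their single orthologue in Northern pike, whose expression profile stands
in for the pre-duplication ancestral state.  Each salmon copy is called
conserved (Pearson r to pike above ``r_conserved``, 0.6 by default, P=0.03
at n=13 tissues) or diverged (r below ``r_diverged``, 0.55, P>0.05); the
band in between is an explicit intermediate class.  Triplets are then
classified, in rule order:

1. both copies conserved                                 -> both_conserved
2. at least one conserved and copies in different
   co-expression clusters                                -> neofunctionalized
3. both diverged, different clusters, and the summed
   FPKM profile conserved with pike                      -> subfunctionalized
4. both diverged and different clusters otherwise        -> diverged_unclassified,
   upgraded to on_off_subfunctionalized when the binary on/off tissue sets of
   the two copies complementarily cover the pike on-set
5. anything else                                         -> intermediate

Rule 1 precedes rule 2 so that pairs where both copies track the ancestral
profile are not swallowed by the one-copy-conserved rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ClusterAssignment

__all__ = [
    "ClassifierConfig",
    "OrthologTriplet",
    "FateCall",
    "FATE_CATEGORIES",
    "pearson_pvalue",
    "conservation_call",
    "summed_profile_conservation",
    "on_off_call",
    "classify_triplet",
    "tissue_specificity",
    "specificity_cluster_test",
]

FATE_CATEGORIES = (
    "both_conserved",
    "neofunctionalized",
    "subfunctionalized",
    "on_off_subfunctionalized",
    "diverged_unclassified",
    "intermediate",
)


@dataclass(frozen=True)
class ClassifierConfig:
    r_conserved: float = 0.6
    r_diverged: float = 0.55
    n_common_tissues: int = 13
    on_off_threshold: float = 1.0  # FPKM

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_diverged <= self.r_conserved <= 1.0:
            raise ValueError("require 0 <= r_diverged <= r_conserved <= 1")


@dataclass
class OrthologTriplet:
    """Two salmon homeolog profiles and the pike orthologue profile.

    ``fpkm_*`` are raw FPKM over the common tissues (same order for all
    three).  Log profiles are derived lazily as log2(FPKM+1).
    """

    gene_a: str
    gene_b: str
    gene_pike: str
    fpkm_a: np.ndarray
    fpkm_b: np.ndarray
    fpkm_pike: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm_a = np.asarray(self.fpkm_a, dtype=float)
        self.fpkm_b = np.asarray(self.fpkm_b, dtype=float)
        self.fpkm_pike = np.asarray(self.fpkm_pike, dtype=float)
        if not (len(self.fpkm_a) == len(self.fpkm_b) == len(self.fpkm_pike)):
            raise ValueError("triplet profiles must have equal tissue length")

    @property
    def log_a(self) -> np.ndarray:
        return np.log2(self.fpkm_a + 1.0)

    @property
    def log_b(self) -> np.ndarray:
        return np.log2(self.fpkm_b + 1.0)

    @property
    def log_pike(self) -> np.ndarray:
        return np.log2(self.fpkm_pike + 1.0)


@dataclass
class FateCall:
    category: str
    status_a: str
    status_b: str
    r_a: float
    r_b: float
    r_sum: float

    def __post_init__(self) -> None:
        if self.category not in FATE_CATEGORIES:
            raise ValueError(f"unknown fate category {self.category!r}")


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation r at sample size n.

    Uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees
    of freedom; r = +/-1 gives p = 0.  At the classifier defaults this
    reproduces the thresholds' printed significance: r=0.6, n=13 -> p=0.030
    and r=0.55, n=13 -> p=0.052 (> 0.05).
    """
    if n < 3:
        raise ValueError("need n >= 3 tissues for a correlation p-value")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; nan when either profile has zero variance."""
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def conservation_call(x: np.ndarray, pike: np.ndarray, cfg: ClassifierConfig) -> tuple[str, float]:
    """Call one salmon copy conserved/diverged/intermediate against pike.

    Profiles are on the log2(FPKM+1) scale.  Returns (status, r);
    zero-variance profiles are 'undefined' with r = nan.
    """
    x = np.asarray(x, dtype=float)
    pike = np.asarray(pike, dtype=float)
    if x.shape != pike.shape:
        raise ValueError("profile length mismatch")
    r = _pearson(x, pike)
    if np.isnan(r):
        return "undefined", r
    if r > cfg.r_conserved:
        return "conserved", r
    if r < cfg.r_diverged:
        return "diverged", r
    return "intermediate", r


def summed_profile_conservation(
    t: OrthologTriplet, cfg: ClassifierConfig
) -> tuple[bool, float]:
    """Is the summed homeolog expression conserved with the ancestral proxy?

    The sum is taken on the FPKM scale (sums of log values have no
    expression meaning), then log-transformed before correlating:
    r_sum = r(log2(A+B+1), log2(pike+1)).  True iff r_sum > r_conserved.
    """
    summed = np.log2(t.fpkm_a + t.fpkm_b + 1.0)
    r_sum = _pearson(summed, t.log_pike)
    if np.isnan(r_sum):
        return False, r_sum
    return bool(r_sum > cfg.r_conserved), r_sum


def on_off_call(t: OrthologTriplet, cfg: ClassifierConfig) -> bool:
    """Binary on/off reading of subfunctionalization.

    Each gene is binarized per tissue (on iff FPKM > on_off_threshold).
    True iff the pike on-set is non-empty, the union of the two salmon
    on-sets covers it, neither copy alone covers it, and both copies are
    expressed somewhere — i.e. the ancestral expression domain is split
    between the copies rather than kept whole by either.
    """
    on_a = set(np.flatnonzero(t.fpkm_a > cfg.on_off_threshold))
    on_b = set(np.flatnonzero(t.fpkm_b > cfg.on_off_threshold))
    on_p = set(np.flatnonzero(t.fpkm_pike > cfg.on_off_threshold))
    if not on_p or not on_a or not on_b:
        return False
    if not on_p <= (on_a | on_b):
        return False
    if on_p <= on_a or on_p <= on_b:
        return False
    return True


def classify_triplet(
    t: OrthologTriplet, clusters: ClusterAssignment, cfg: ClassifierConfig | None = None
) -> FateCall:
    """Assign a fate category to one ortholog triplet (see module rules)."""
    cfg = cfg or ClassifierConfig()
    if t.gene_a not in clusters or t.gene_b not in clusters:
        missing = [g for g in (t.gene_a, t.gene_b) if g not in clusters]
        raise KeyError(f"salmon gene(s) without cluster label: {missing}")
    status_a, r_a = conservation_call(t.log_a, t.log_pike, cfg)
    status_b, r_b = conservation_call(t.log_b, t.log_pike, cfg)
    different_clusters = clusters[t.gene_a] != clusters[t.gene_b]
    sum_conserved, r_sum = summed_profile_conservation(t, cfg)

    if status_a == "conserved" and status_b == "conserved":
        category = "both_conserved"
    elif ("conserved" in (status_a, status_b)) and different_clusters:
        category = "neofunctionalized"
    elif status_a == "diverged" and status_b == "diverged" and different_clusters:
        if sum_conserved:
            category = "subfunctionalized"
        elif on_off_call(t, cfg):
            category = "on_off_subfunctionalized"
        else:
            category = "diverged_unclassified"
    else:
        category = "intermediate"
    return FateCall(category, status_a, status_b, r_a, r_b, r_sum)


def tissue_specificity(x: np.ndarray) -> float:
    """Expression specificity tau in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (N - 1): 0 for a uniform profile, 1 for
    a one-hot profile, invariant under positive scaling.  Undefined (nan)
    for an all-zero profile.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("specificity needs a 1-d profile with >= 2 samples")
    if (x < 0).any():
        raise ValueError("specificity requires a non-negative profile")
    xmax = x.max()
    if xmax == 0.0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (len(x) - 1))


def specificity_cluster_test(
    clusters: ClusterAssignment, scores: dict[str, float]
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of specificity between clusters.

    Returns one row per cluster pair with the member counts and p-value.
    Clusters with no scored genes are skipped with a warning.
    """
    by_cluster: dict[int, list[float]] = {}
    for gene, label in clusters.labels.items():
        s = scores.get(gene)
        if s is not None and not np.isnan(s):
            by_cluster.setdefault(label, []).append(s)
    empty = sorted(set(range(1, clusters.k + 1)) - set(by_cluster))
    if empty:
        warnings.warn(f"clusters without scored genes skipped: {empty}", stacklevel=2)
    rows = []
    for i, j in itertools.combinations(sorted(by_cluster), 2):
        # exact rank-sum distribution for small tie-free samples, normal
        # approximation otherwise (scipy's auto policy)
        res = stats.mannwhitneyu(
            by_cluster[i], by_cluster[j], alternative="two-sided", method="auto"
        )
        rows.append((i, j, len(by_cluster[i]), len(by_cluster[j]), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["cluster_i", "cluster_j", "n_i", "n_j", "p_value"])
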
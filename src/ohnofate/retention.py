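"""Duplicate-retention analysis from rooted gene trees.

Salmonids carry two nested whole-genome duplications: the teleost-specific
Ts3R (~320 Mya, shared with zebrafish and pike) and the salmonid-specific
Ss4R (~80-100 Mya, after the pike split, before the salmon-trout split).
Given rooted gene-family trees whose leaves are labeled
``species|gene|chromosome``, this module

* labels internal nodes as duplication or speciation by the species-overlap
  criterion (duplication iff the species sets of the two child subtrees
  intersect),
* assigns each duplication an era — Ts3R, pre-Ss4R small-scale duplication
  (SSD), Ss4R, or post-Ss4R SSD — by mapping it to the species tree, with
  salmon-only duplications disambiguated by chromosome (same chromosome for
  the two salmon copies -> SSD, different chromosomes -> Ss4R) and at most
  one Ss4R allowed per root-to-leaf path (the oldest candidate keeps it),
* tabulates retention of each era's duplicates conditional on whether the
  ancestral event's duplicate was itself retained, and
* provides the significance machinery used on those counts: a pooled
  two-proportion z-test (Bonferroni alpha 0.001/7), odds-ratio / relative
  risk with Wald intervals, and a co-retention test for interaction
  partners.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesTree",
    "GeneTree",
    "ConditionalRetentionTable",
    "BONFERRONI_ALPHA",
    "parse_gene_tree",
    "read_gene_trees",
    "label_duplication_nodes",
    "assign_era",
    "retention_conditional_table",
    "gene_retention_flags",
    "enumerate_rooted_trees",
    "two_proportion_z",
    "odds_ratio_rr",
    "co_retention_test",
]

# seven retention comparisons at the study-wide 0.001 level
BONFERRONI_ALPHA = 0.001 / 7

ERAS = ("none", "Ts3R", "preSs4R_SSD", "Ss4R", "postSs4R_SSD", "ambiguous")


@dataclass
class SpeciesTree:
    """Rooted species tree with the WGD markers.

    ``ts3r_species`` spans the clade whose root carries the teleost WGD;
    ``ss4r_species`` spans the clade whose stem branch carries the salmonid
    WGD; ``duplicated_species`` is the extant tetraploid-descendant species
    whose chromosomes drive the SSD/Ss4R disambiguation rule.
    """

    tree: dendropy.Tree
    duplicated_species: str = "salmon"
    sister_species: str = "trout"

    @classmethod
    def default(cls) -> "SpeciesTree":
        t = dendropy.Tree.get(
            data="(zebrafish,(pike,(salmon,trout)));", schema="newick"
        )
        t.is_rooted = True
        return cls(tree=t)

    @property
    def species(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def mrca(self, species: set[str]) -> dendropy.Node:
        if len(species) == 1:
            (sp,) = species
            for leaf in self.tree.leaf_node_iter():
                if leaf.taxon.label == sp:
                    return leaf
            raise KeyError(sp)
        return self.tree.mrca(taxon_labels=sorted(species))

    def _named_node(self, labels: set[str]) -> dendropy.Node:
        return self.tree.mrca(taxon_labels=sorted(labels))

    @property
    def ts3r_node(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def ss4r_crown(self) -> dendropy.Node:
        """MRCA of the duplicated species and its sister (salmon-trout crown)."""
        return self._named_node({self.duplicated_species, self.sister_species})


@dataclass
class GeneTree:
    """Rooted binary gene tree with per-leaf (species, gene, chromosome).

    Internal nodes gain ``event`` ('duplication'|'speciation') after
    :func:`label_duplication_nodes` and ``era`` after :func:`assign_era`.
    """

    tree: dendropy.Tree
    family_id: str = ""
    root_was_polytomy: bool = False

    def leaves(self):
        return list(self.tree.leaf_node_iter())

    def internal_nodes(self):
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    def species_below(self, node: dendropy.Node) -> set[str]:
        return {l.species for l in node.leaf_iter()}

    def genes_for(self, species: str) -> list[str]:
        return [l.gene for l in self.leaves() if l.species == species]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _resolve_polytomies(node: dendropy.Node) -> bool:
    """Make the subtree binary by grouping the first two children repeatedly.

    Deterministic given input child order; returns True if any resolution
    happened.
    """
    changed = False
    for child in list(node.child_nodes()):
        changed |= _resolve_polytomies(child)
    while len(node.child_nodes()) > 2:
        changed = True
        kids = node.child_nodes()
        grouped = dendropy.Node()
        first, second = kids[0], kids[1]
        node.remove_child(first)
        node.remove_child(second)
        grouped.add_child(first)
        grouped.add_child(second)
        node.insert_child(0, grouped)
    return changed


def parse_gene_tree(
    newick: str, species_tree: SpeciesTree | None = None, family_id: str = ""
) -> GeneTree:
    """Parse one Newick string with ``species|gene|chromosome`` leaf labels.

    The chromosome field may be empty or absent for species where it is not
    used.  A root polytomy (or any internal polytomy) is resolved
    deterministically by grouping the first two children, and flagged.
    Leaves whose species is not in the species tree raise, naming the leaf.
    """
    species_tree = species_tree or SpeciesTree.default()
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    known = species_tree.species
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        parts = label.split("|")
        if len(parts) == 2:
            sp, gene = parts
            chrom = None
        elif len(parts) == 3:
            sp, gene, chrom = parts
            chrom = chrom or None
        else:
            raise ValueError(
                f"leaf {label!r} does not follow the species|gene|chromosome convention"
            )
        if sp not in known:
            raise ValueError(f"unknown species {sp!r} in leaf {label!r}")
        leaf.species = sp
        leaf.gene = gene
        leaf.chromosome = chrom
    was_poly = _resolve_polytomies(tree.seed_node)
    if was_poly:
        warnings.warn(
            f"polytomy in gene tree {family_id or newick[:40]!r} resolved "
            "deterministically (first two children grouped)",
            stacklevel=2,
        )
    return GeneTree(tree=tree, family_id=family_id, root_was_polytomy=was_poly)


def read_gene_trees(path, species_tree: SpeciesTree | None = None) -> list[GeneTree]:
    """Read a file with one Newick tree per line."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            out.append(parse_gene_tree(line, species_tree, family_id=f"fam{i:05d}"))
    return out


def label_duplication_nodes(g: GeneTree) -> GeneTree:
    """Species-overlap event labeling.

    An internal node is a duplication iff the species sets of its two child
    subtrees intersect; otherwise it is a speciation.  This is the standard
    deterministic criterion for event calling on a fixed rooted gene tree.
    """
    for node in g.tree.postorder_node_iter():
        if node.is_leaf():
            node._species_set = {node.species}
            continue
        kids = node.child_nodes()
        union: set[str] = set()
        overlap = False
        for c in kids:
            if union & c._species_set:
                overlap = True
            union |= c._species_set
        node._species_set = union
        node.event = "duplication" if overlap else "speciation"
    return g


def _salmon_chromosomes(node: dendropy.Node, species: str) -> set[str]:
    return {
        l.chromosome for l in node.leaf_iter() if l.species == species and l.chromosome
    }


def assign_era(g: GeneTree, s: SpeciesTree | None = None) -> GeneTree:
    """Assign a duplication era to every labeled node.

    Duplications are mapped onto the species tree by the MRCA of their
    descendant species: the teleost root -> Ts3R; the salmon-trout crown
    (i.e. the duplication predates the salmon-trout split but postdates the
    pike split) -> Ss4R; the pike+salmonid ancestor -> pre-Ss4R SSD.
    Salmon-only duplications are ambiguous between Ss4R (with the trout
    orthologue lost) and a post-Ss4R SSD; they are resolved by the
    chromosome rule: same chromosome for the two salmon subtrees -> SSD,
    different chromosomes -> Ss4R.  A subtree whose salmon leaves span
    several chromosomes stays 'ambiguous' and is excluded from counts.
    Because only a single Ss4R occurred along any lineage, when several
    Ss4R-classified nodes are nested the oldest (closest to the root) keeps
    Ss4R and the rest become post-Ss4R SSDs.
    """
    s = s or SpeciesTree.default()
    dup_sp = s.duplicated_species
    root = s.tree.seed_node
    crown = s.ss4r_crown
    # species-tree nodes strictly between the teleost root and the salmonid
    # crown host pre-Ss4R small-scale duplications
    mid_nodes = set()
    n = crown.parent_node
    while n is not None and n is not root:
        mid_nodes.add(n)
        n = n.parent_node

    for node in g.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if getattr(node, "event", None) != "duplication":
            node.era = "none"
            continue
        species = g.species_below(node)
        m = s.mrca(species)
        if m is root:
            node.era = "Ts3R"
        elif m is crown:
            node.era = "Ss4R"
        elif m in mid_nodes:
            node.era = "preSs4R_SSD"
        elif species == {dup_sp}:
            chroms = [_salmon_chromosomes(c, dup_sp) for c in node.child_nodes()]
            if any(len(ch) != 1 for ch in chroms):
                node.era = "ambiguous"
            elif chroms[0] == chroms[1]:
                node.era = "postSs4R_SSD"
            else:
                node.era = "Ss4R"
        else:
            # lineage-specific duplication in a non-focal species
            node.era = "none"

    # enforce a single Ss4R per root-to-leaf path: preorder guarantees we
    # meet the oldest candidate first
    for node in g.tree.preorder_node_iter():
        if node.is_leaf() or getattr(node, "era", "none") != "Ss4R":
            continue
        anc = node.parent_node
        while anc is not None:
            if getattr(anc, "era", "none") == "Ss4R":
                node.era = "postSs4R_SSD"
                break
            anc = anc.parent_node
    return g


@dataclass
class ConditionalRetentionTable:
    """Retention counts per era, conditioned on the ancestral event's fate.

    An 'opportunity' is a lineage whose parent duplicate survived into the
    relevant era (a family with any salmon gene has a Ts3R opportunity; each
    surviving post-Ts3R lineage has one Ss4R opportunity; each surviving
    post-Ss4R gene lineage has one SSD opportunity).
    """

    counts: pd.DataFrame  # columns: event, condition, retained, opportunities

    def fraction(self, event: str, condition: str = "all") -> float:
        row = self.counts[
            (self.counts.event == event) & (self.counts.condition == condition)
        ]
        if row.empty:
            raise KeyError((event, condition))
        r, n = int(row.retained.iloc[0]), int(row.opportunities.iloc[0])
        return r / n if n else float("nan")

    def row(self, event: str, condition: str = "all") -> tuple[int, int]:
        rows = self.counts[
            (self.counts.event == event) & (self.counts.condition == condition)
        ]
        if rows.empty:
            raise KeyError((event, condition))
        return int(rows.retained.iloc[0]), int(rows.opportunities.iloc[0])

    def write(self, path) -> None:
        out = self.counts.copy()
        out["fraction"] = out.retained / out.opportunities.replace(0, np.nan)
        out.to_csv(path, sep="\t", index=False)


def _has_era(node: dendropy.Node, era: str) -> bool:
    for n in node.preorder_iter():
        if not n.is_leaf() and getattr(n, "era", "none") == era:
            return True
    return False


def _oldest_nodes_with_era(node: dendropy.Node, era: str) -> list[dendropy.Node]:
    """Maximal (non-nested) nodes below ``node`` carrying ``era``."""
    found: list[dendropy.Node] = []

    def walk(n: dendropy.Node) -> None:
        if not n.is_leaf() and getattr(n, "era", "none") == era:
            found.append(n)
            return
        for c in n.child_nodes():
            walk(c)

    walk(node)
    return found


def retention_conditional_table(
    trees: list[GeneTree], s: SpeciesTree | None = None
) -> ConditionalRetentionTable:
    """Tabulate duplicate retention per era, conditioned on ancestor retention.

    Per family: the Ts3R duplicate is retained iff the tree contains a
    Ts3R-labeled duplication (both post-Ts3R lineages survived).  Each
    surviving post-Ts3R lineage containing salmon genes is one Ss4R
    opportunity, retained iff an Ss4R node lies within it; the conditional
    rows split those opportunities by whether the Ts3R duplicate of their
    family was retained.  Post-Ss4R SSD opportunities are the surviving
    post-Ss4R gene lineages, split by Ss4R retention.
    """
    s = s or SpeciesTree.default()
    dup_sp = s.duplicated_species
    tallies = {
        ("Ts3R", "all"): [0, 0],
        ("Ss4R", "all"): [0, 0],
        ("Ss4R", "Ts3R_retained"): [0, 0],
        ("Ss4R", "Ts3R_lost"): [0, 0],
        ("postSs4R_SSD", "all"): [0, 0],
        ("postSs4R_SSD", "Ss4R_retained"): [0, 0],
        ("postSs4R_SSD", "Ss4R_lost"): [0, 0],
    }

    def bump(key: tuple[str, str], retained: bool) -> None:
        tallies[key][0] += int(retained)
        tallies[key][1] += 1

    for g in trees:
        root = g.tree.seed_node
        if not any(l.species == dup_sp for l in root.leaf_iter()):
            continue  # no salmon representation: no retention opportunity
        ts3r_nodes = _oldest_nodes_with_era(root, "Ts3R")
        ts3r_retained = bool(ts3r_nodes)
        bump(("Ts3R", "all"), ts3r_retained)

        # post-Ts3R lineages with an Ss4R opportunity
        if ts3r_retained:
            lineages = [c for n in ts3r_nodes for c in n.child_nodes()]
        else:
            lineages = [root]
        ts3r_cond = "Ts3R_retained" if ts3r_retained else "Ts3R_lost"
        for lin in lineages:
            if not any(l.species == dup_sp for l in lin.leaf_iter()):
                continue
            ss4r_nodes = _oldest_nodes_with_era(lin, "Ss4R")
            ss4r_retained = bool(ss4r_nodes)
            bump(("Ss4R", "all"), ss4r_retained)
            bump(("Ss4R", ts3r_cond), ss4r_retained)

            # post-Ss4R gene lineages with an SSD opportunity
            if ss4r_retained:
                sub_lineages = [c for n in ss4r_nodes for c in n.child_nodes()]
            else:
                sub_lineages = [lin]
            ss4r_cond = "Ss4R_retained" if ss4r_retained else "Ss4R_lost"
            for sub in sub_lineages:
                if not any(l.species == dup_sp for l in sub.leaf_iter()):
                    continue
                ssd = _has_era(sub, "postSs4R_SSD")
                bump(("postSs4R_SSD", "all"), ssd)
                bump(("postSs4R_SSD", ss4r_cond), ssd)

    rows = [
        {"event": e, "condition": c, "retained": r, "opportunities": n}
        for (e, c), (r, n) in tallies.items()
    ]
    return ConditionalRetentionTable(counts=pd.DataFrame(rows))


def gene_retention_flags(trees: list[GeneTree], era: str = "Ss4R",
                         s: SpeciesTree | None = None) -> dict[str, bool]:
    """Per salmon gene: does a duplication of ``era`` lie on its root path?"""
    s = s or SpeciesTree.default()
    flags: dict[str, bool] = {}
    for g in trees:
        for leaf in g.leaves():
            if leaf.species != s.duplicated_species:
                continue
            retained = False
            n = leaf.parent_node
            while n is not None:
                if getattr(n, "era", "none") == era:
                    retained = True
                    break
                n = n.parent_node
            flags[leaf.gene] = retained
    return flags


def enumerate_rooted_trees(leaves: list[str]):
    """Yield every rooted binary tree shape over the labeled leaves, as Newick
    fragments (no trailing semicolon).  (2n-3)!! shapes for n leaves; used to
    validate event labeling exhaustively on small leaf sets."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, r):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in enumerate_rooted_trees([first, *left_rest]):
                for rt in enumerate_rooted_trees(right):
                    yield f"({lt},{rt})"


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Pooled two-proportion z-test with two-sided normal p-value.

    Returns z, p, the two proportions, and a significance flag at the
    Bonferroni-corrected level alpha = 0.001/7.  When the pooled proportion
    is degenerate (0 or 1) the difference is necessarily 0 and z is defined
    as 0, flagged.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    degenerate = pooled in (0.0, 1.0)
    if degenerate:
        z = 0.0
    else:
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (p1 - p2) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "z": float(z),
        "p": p,
        "p1": p1,
        "p2": p2,
        "alpha": BONFERRONI_ALPHA,
        "significant": p < BONFERRONI_ALPHA,
        "degenerate": degenerate,
    }


def odds_ratio_rr(table: list[list[float]] | np.ndarray) -> dict:
    """Odds ratio and relative risk for a 2x2 table [[a, b], [c, d]].

    Rows are groups, columns retained/lost.  A Haldane-Anscombe 0.5
    correction is applied to the odds ratio when any cell is zero
    (flagged); the p-value is a two-sided Wald test on log OR.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    (a, b), (c, d) = t
    if a + b == 0 or c + d == 0:
        raise ValueError("empty row in 2x2 table")
    corrected = 0.0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if corrected else (a, b, c, d)
    odds_ratio = (aa * dd) / (bb * cc)
    rr = (a / (a + b)) / (c / (c + d)) if c > 0 else float("inf")
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = math.log(odds_ratio) / se_log if odds_ratio > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    lo, hi = (
        math.exp(math.log(odds_ratio) - 1.959963984540054 * se_log),
        math.exp(math.log(odds_ratio) + 1.959963984540054 * se_log),
    )
    return {
        "odds_ratio": float(odds_ratio),
        "relative_risk": float(rr),
        "p": p,
        "ci95": (float(lo), float(hi)),
        "corrected": corrected,
    }


def co_retention_test(
    retention: dict[str, bool], pairs: list[tuple[str, str]]
) -> dict:
    """Do interaction partners share their retention fate more than expected?

    For every ordered (focal, partner) direction of each pair, the partner's
    retention is cross-tabulated against the focal gene's retention:
    [[both retained, focal retained only], [partner retained only, both
    lost]].  Under independence the odds ratio is ~1.  Pairs naming a gene
    without a retention status are skipped and counted.
    """
    if not pairs:
        raise ValueError("empty partner list")
    a = b = c = d = 0
    skipped = 0
    for g1, g2 in pairs:
        if g1 not in retention or g2 not in retention:
            skipped += 1
            continue
        for focal, partner in ((g1, g2), (g2, g1)):
            if retention[focal]:
                if retention[partner]:
                    a += 1
                else:
                    b += 1
            else:
                if retention[partner]:
                    c += 1
                else:
                    d += 1
    table = [[a, b], [c, d]]
    out = {"table": table, "skipped": skipped}
    out["odds_ratio_rr"] = odds_ratio_rr(table)
    out["two_proportion_z"] = two_proportion_z(a, a + b, c, c + d) if (a + b and c + d) else None
    return out
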
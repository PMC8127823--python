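import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ohnofate import (
    BONFERRONI_ALPHA,
    SimConfig,
    enumerate_rooted_trees,
    SpeciesTree,
    assign_era,
    co_retention_test,
    gene_retention_flags,
    label_duplication_nodes,
    odds_ratio_rr,
    parse_gene_tree,
    retention_conditional_table,
    simulate_gene_families,
    two_proportion_z,
)


def annotated(newick: str, stree: SpeciesTree):
    g = parse_gene_tree(newick, stree)
    return assign_era(label_duplication_nodes(g), stree)


def eras_of(g):
    return [getattr(n, "era", "none") for n in g.internal_nodes()]


# ---------------------------------------------------------------------------
# parsing


class TestParsing:
    def test_round_trip(self, stree):
        g = parse_gene_tree("((salmon|g1|ssa01,salmon|g2|ssa05),pike|g3|c1);", stree)
        leaves = g.leaves()
        assert len(leaves) == 3
        assert {l.species for l in leaves} == {"salmon", "pike"}
        assert leaves[0].chromosome == "ssa01"
        # write then parse again: same leaf set and topology depth
        g2 = parse_gene_tree(g.newick(), stree)
        assert {l.gene for l in g2.leaves()} == {l.gene for l in g.leaves()}

    def test_malformed_newick(self, stree):
        with pytest.raises(ValueError, match="malformed"):
            parse_gene_tree("((salmon|g1|ssa01,;", stree)

    def test_unknown_species_named(self, stree):
        with pytest.raises(ValueError, match="tilapia"):
            parse_gene_tree("(tilapia|g1|c1,pike|g2|c2);", stree)

    def test_polytomy_resolved_deterministically(self, stree):
        with pytest.warns(UserWarning, match="polytomy"):
            g = parse_gene_tree("(salmon|a|ssa01,trout|b|,pike|c|);", stree)
        assert all(len(n.child_nodes()) == 2 for n in g.internal_nodes())
        assert g.root_was_polytomy


# ---------------------------------------------------------------------------
# event labeling


class TestSpeciesOverlap:
    @pytest.mark.parametrize(
        "newick,root_event",
        [
            ("((salmon|a|ssa01,trout|b|),(salmon|c|ssa02,trout|d|));", "duplication"),
            ("((salmon|a|ssa01,trout|b|),pike|c|);", "speciation"),
            ("(salmon|a|ssa01,salmon|b|ssa01);", "duplication"),
        ],
    )
    def test_root_event(self, stree, newick, root_event):
        g = label_duplication_nodes(parse_gene_tree(newick, stree))
        assert g.tree.seed_node.event == root_event

    def test_overlap_implies_reconciliation_duplication(self, stree):
        """Species overlap is strictly conservative w.r.t. LCA reconciliation:
        every overlap duplication is a reconciliation duplication, but
        discordant topologies force extra reconciliation duplications."""
        some_extra = 0
        for g, lca_dup in _all_five_leaf_trees_with_oracle(stree):
            for node in g.internal_nodes():
                if node.event == "duplication":
                    assert lca_dup[id(node)]
                elif lca_dup[id(node)]:
                    some_extra += 1
        assert some_extra > 0  # the criteria genuinely differ on discordant trees

    def test_equivalence_on_concordant_trees(self, stree):
        """On gene trees concordant with the species tree the two criteria agree."""
        concordant = [
            "(zebrafish|z|,(pike|p|,(salmon|a|ssa01,trout|t|)));",
            "(zebrafish|z|,(pike|p|,((salmon|a|ssa01,trout|t1|),(salmon|b|ssa02,trout|t2|))));",
            "((zebrafish|z1|,(pike|p1|,(salmon|a|ssa01,trout|t1|))),"
            "(zebrafish|z2|,(pike|p2|,(salmon|b|ssa02,trout|t2|))));",
            "(zebrafish|z|,(pike|p|,((salmon|a|ssa01,salmon|b|ssa01),trout|t|)));",
        ]
        for nwk in concordant:
            g = label_duplication_nodes(parse_gene_tree(nwk, stree))
            lca = _strict_lca_duplications(g, stree)
            for node in g.internal_nodes():
                assert (node.event == "duplication") == lca[id(node)], nwk


def _strict_lca_duplications(g, stree):
    """Classic LCA-mapping reconciliation: duplication iff M(v) == M(child)."""
    m = {}
    out = {}
    for node in g.tree.postorder_node_iter():
        if node.is_leaf():
            m[id(node)] = stree.mrca({node.species})
            continue
        c1, c2 = node.child_nodes()
        m[id(node)] = stree.mrca({l.species for l in node.leaf_iter()})
        out[id(node)] = m[id(node)] is m[id(c1)] or m[id(node)] is m[id(c2)]
    return out


FIVE_LEAVES = ["salmon|g1|ssa01", "salmon|g2|ssa05", "trout|g3|", "pike|g4|", "zebrafish|g5|"]


def _all_five_leaf_trees_with_oracle(stree):
    for nwk in enumerate_rooted_trees(FIVE_LEAVES):
        g = label_duplication_nodes(parse_gene_tree(nwk + ";", stree))
        yield g, _strict_lca_duplications(g, stree)


# ---------------------------------------------------------------------------
# era assignment


class TestEraAssignment:
    def test_ss4r_with_trout_on_both_sides(self, stree):
        g = annotated(
            "(pike|p|,((salmon|a|ssa01,trout|t1|),(salmon|b|ssa02,trout|t2|)));", stree
        )
        assert "Ss4R" in eras_of(g)

    def test_salmon_only_different_chromosomes_is_ss4r(self, stree):
        g = annotated("(pike|p|,(salmon|a|ssa03,salmon|b|ssa06));", stree)
        assert "Ss4R" in eras_of(g)

    def test_salmon_only_same_chromosome_is_ssd(self, stree):
        g = annotated("(pike|p|,(salmon|a|ssa03,salmon|b|ssa03));", stree)
        assert "postSs4R_SSD" in eras_of(g)
        assert "Ss4R" not in eras_of(g)

    def test_ts3r_at_teleost_root(self, stree):
        g = annotated(
            "((zebrafish|z1|,(pike|p1|,salmon|a|ssa01)),"
            "(zebrafish|z2|,(pike|p2|,salmon|b|ssa02)));",
            stree,
        )
        assert g.tree.seed_node.era == "Ts3R"

    def test_pre_ss4r_ssd_between_root_and_stem(self, stree):
        g = annotated(
            "(zebrafish|z|,((pike|p1|,salmon|a|ssa01),(pike|p2|,salmon|b|ssa02)));", stree
        )
        assert "preSs4R_SSD" in eras_of(g)

    def test_nested_ss4r_demoted_to_ssd(self, stree):
        # two nested duplications both mapping to the salmon-trout crown:
        # only the oldest (closest to the root) keeps Ss4R
        g = annotated(
            "(pike|p|,(((salmon|a|ssa01,trout|ta|),(salmon|b|ssa05,trout|tb|)),"
            "(salmon|c|ssa09,trout|tc|)));",
            stree,
        )
        eras = eras_of(g)
        assert eras.count("Ss4R") == 1
        assert "postSs4R_SSD" in eras

    def test_multichromosome_subtree_ambiguous(self, stree):
        g = annotated(
            "(pike|p|,((salmon|a|ssa01,salmon|b|ssa05),salmon|c|ssa01));", stree
        )
        # the inner (ssa01, ssa05) node takes Ss4R; the outer node has a
        # multi-chromosome child and stays ambiguous
        assert "ambiguous" in eras_of(g)

    def test_single_ss4r_per_path_invariant_on_simulated_trees(self, stree):
        fams = simulate_gene_families(SimConfig(n_families=150, seed=21, ssd_rate=0.5))
        for nwk in fams.newicks:
            g = annotated(nwk, stree)
            for leaf in g.leaves():
                n_ss4r = 0
                node = leaf.parent_node
                while node is not None:
                    n_ss4r += getattr(node, "era", "none") == "Ss4R"
                    node = node.parent_node
                assert n_ss4r <= 1


# ---------------------------------------------------------------------------
# conditional retention


class TestConditionalRetention:
    def test_all_retained_gives_fraction_one(self, stree):
        lin = "(zebrafish|z{0}|,(pike|p{0}|,((salmon|a{0}|ssa01,trout|t{0}a|),(salmon|b{0}|ssa05,trout|t{0}b|))))"
        nwk = f"({lin.format(1)},{lin.format(2)});"
        trees = [annotated(nwk, stree) for _ in range(3)]
        table = retention_conditional_table(trees, stree)
        assert table.fraction("Ts3R") == 1.0
        assert table.fraction("Ss4R", "Ts3R_retained") == 1.0

    def test_no_duplications_reported_undefined(self, stree):
        g = annotated("(zebrafish|z|,(pike|p|,(salmon|a|ssa01,trout|t|)));", stree)
        table = retention_conditional_table([g], stree)
        assert table.fraction("Ts3R") == 0.0
        assert math.isnan(table.fraction("Ss4R", "Ts3R_retained"))

    def test_gene_retention_flags(self, stree):
        g = annotated("(pike|p|,(salmon|a|ssa03,salmon|b|ssa06));", stree)
        flags = gene_retention_flags([g], era="Ss4R")
        assert flags == {"a": True, "b": True}
        g2 = annotated("(pike|p|,(salmon|a|ssa03,trout|t|));", stree)
        assert gene_retention_flags([g2], era="Ss4R") == {"a": False}


# ---------------------------------------------------------------------------
# statistics


class TestTwoProportionZ:
    def test_equal_proportions(self):
        out = two_proportion_z(5, 10, 5, 10)
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_hand_computed_example(self):
        # pooled p = 0.5, se = sqrt(0.5*0.5*0.2) = sqrt(0.05)
        out = two_proportion_z(8, 10, 2, 10)
        assert out["z"] == pytest.approx(0.6 / math.sqrt(0.05), abs=1e-9)
        assert out["z"] == pytest.approx(2.683, abs=1e-3)
        assert out["p"] == pytest.approx(0.0073, abs=1e-4)

    def test_bonferroni_alpha(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.001 / 7)
        assert two_proportion_z(8, 10, 2, 10)["significant"] is False

    def test_p_matches_normal_cdf_identity(self):
        for x1, n1, x2, n2 in [(8, 10, 2, 10), (30, 50, 20, 60), (1, 9, 7, 11)]:
            out = two_proportion_z(x1, n1, x2, n2)
            assert out["p"] == pytest.approx(2 * stats.norm.cdf(-abs(out["z"])), abs=1e-12)

    def test_degenerate_pool_flagged(self):
        out = two_proportion_z(0, 5, 0, 7)
        assert out["degenerate"] and out["z"] == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_proportion_z(5, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_z(5, 3, 1, 2)


class TestOddsRatioRR:
    def test_hand_example(self):
        out = odds_ratio_rr([[8, 2], [2, 8]])
        assert out["odds_ratio"] == pytest.approx(16.0)
        assert out["relative_risk"] == pytest.approx(4.0)
        assert not out["corrected"]

    def test_null_table(self):
        out = odds_ratio_rr([[5, 5], [5, 5]])
        assert out["odds_ratio"] == 1.0
        assert out["relative_risk"] == 1.0
        assert out["p"] == pytest.approx(1.0)

    def test_haldane_anscombe_correction(self):
        out = odds_ratio_rr([[1, 0], [0, 1]])
        assert out["corrected"]
        assert out["odds_ratio"] == pytest.approx((1.5 * 1.5) / (0.5 * 0.5))

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty row"):
            odds_ratio_rr([[0, 0], [3, 4]])


class TestCoRetention:
    def test_independent_retention_or_near_one(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(2000)]
        retention = {g: bool(rng.random() < 0.5) for g in genes}
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(1000)]
        out = co_retention_test(retention, pairs)
        lo, hi = out["odds_ratio_rr"]["ci95"]
        assert lo <= 1.0 <= hi

    def test_perfect_co_retention_significant(self):
        rng = np.random.default_rng(3)
        retention = {}
        pairs = []
        for i in range(200):
            status = bool(rng.random() < 0.5)
            retention[f"a{i}"] = status
            retention[f"b{i}"] = status
            pairs.append((f"a{i}", f"b{i}"))
        out = co_retention_test(retention, pairs)
        assert out["odds_ratio_rr"]["odds_ratio"] > 1.0
        assert out["two_proportion_z"]["p"] < BONFERRONI_ALPHA

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            co_retention_test({"a": True}, [])

    def test_unknown_gene_skipped(self):
        out = co_retention_test(
            {"a": True, "b": True, "c": False, "d": False},
            [("a", "b"), ("c", "d"), ("a", "zz")],
        )
        assert out["skipped"] == 1
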
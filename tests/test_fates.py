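import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohnofate import (
    ClassifierConfig,
    ClusterAssignment,
    OrthologTriplet,
    classify_triplet,
    conservation_call,
    on_off_call,
    pearson_pvalue,
    specificity_cluster_test,
    summed_profile_conservation,
    tissue_specificity,
)
from tests.conftest import profile_with_r

CFG = ClassifierConfig()


class TestPearsonPvalue:
    def test_threshold_06_prints_003(self):
        assert round(pearson_pvalue(0.6, 13), 2) == 0.03

    def test_threshold_06_exact_t_cdf(self):
        # independent oracle: t CDF via the incomplete-beta identity
        from scipy.special import betainc

        r, n = 0.6, 13
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p_oracle = betainc((n - 2) / 2.0, 0.5, (n - 2) / ((n - 2) + t * t))
        assert pearson_pvalue(0.6, 13) == pytest.approx(p_oracle, abs=1e-12)
        assert pearson_pvalue(0.6, 13) == pytest.approx(0.0302, abs=5e-4)

    def test_threshold_055_above_005(self):
        assert pearson_pvalue(0.55, 13) > 0.05

    def test_zero_correlation(self):
        assert pearson_pvalue(0.0, 13) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [1.0, -1.0])
    def test_perfect_correlation(self, r):
        assert pearson_pvalue(r, 13) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.95, 10)
        ps = [pearson_pvalue(r, 13) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = range(4, 30)
        pn = [pearson_pvalue(0.5, n) for n in ns]
        assert all(a > b for a, b in zip(pn, pn[1:]))


class TestConservationCall:
    def test_identical_profile_conserved(self):
        pike = np.array([1.0, 4.0, 2.0, 5.0])
        assert conservation_call(pike, pike, CFG)[0] == "conserved"

    def test_constant_profile_undefined(self):
        pike = np.array([1.0, 4.0, 2.0, 5.0])
        status, r = conservation_call(np.full(4, 3.0), pike, CFG)
        assert status == "undefined" and np.isnan(r)

    def test_intermediate_band(self):
        x, pike = profile_with_r(0.58)
        status, r = conservation_call(x, pike, CFG)
        assert status == "intermediate"
        assert r == pytest.approx(0.58, abs=1e-9)

    def test_diverged_below_band(self):
        x, pike = profile_with_r(0.30)
        assert conservation_call(x, pike, CFG)[0] == "diverged"

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            conservation_call(np.ones(3), np.ones(4), CFG)


class TestSummedProfileConservation:
    def test_exact_partition_gives_r_one(self):
        pike = np.array([0.0, 4.0, 9.0, 2.0, 7.0])
        a = np.array([0.0, 4.0, 0.0, 2.0, 0.0])
        b = pike - a
        t = OrthologTriplet("a", "b", "p", a, b, pike)
        ok, r_sum = summed_profile_conservation(t, CFG)
        assert ok and r_sum == pytest.approx(1.0)

    def test_all_zero_copies_false(self):
        pike = np.array([0.0, 4.0, 9.0])
        t = OrthologTriplet("a", "b", "p", np.zeros(3), np.zeros(3), pike)
        ok, r_sum = summed_profile_conservation(t, CFG)
        assert not ok  # zero-variance sum has no defined correlation


class TestOnOffCall:
    def _triplet(self, on_a, on_b, on_pike, n=8):
        def fpkm(on):
            x = np.zeros(n)
            x[list(on)] = 5.0
            return x

        return OrthologTriplet("a", "b", "p", fpkm(on_a), fpkm(on_b), fpkm(on_pike))

    def test_perfect_partition(self):
        t = self._triplet({0, 1, 2}, {3, 4, 5}, {0, 1, 2, 3, 4, 5})
        assert on_off_call(t, CFG)

    def test_single_copy_covers_ancestor(self):
        t = self._triplet({0, 1, 2}, set(), {0, 1, 2})
        assert not on_off_call(t, CFG)

    def test_overlapping_cover(self):
        t = self._triplet({0, 1}, {1, 2}, {0, 1, 2})
        assert on_off_call(t, CFG)

    def test_union_not_covering(self):
        t = self._triplet({0}, {1}, {0, 1, 2})
        assert not on_off_call(t, CFG)


class TestClassifyTriplet:
    def _clusters(self, la, lb):
        labels = {"a": la, "b": lb}
        # pad so labels 1..k are all occupied
        k = max(la, lb)
        for fill in range(1, k + 1):
            labels[f"pad{fill}"] = fill
        return ClusterAssignment(labels=labels, k=k)

    def test_conserved_triplet(self):
        pike = np.array([1.0, 8.0, 0.0, 5.0, 3.0, 2.0, 7.0, 1.0, 0.0, 4.0, 6.0, 2.0, 3.0])
        t = OrthologTriplet("a", "b", "p", pike, pike, pike)
        call = classify_triplet(t, self._clusters(1, 1), CFG)
        assert call.category == "both_conserved"

    def test_conserved_wins_over_neofunctionalized_rule(self):
        # both conserved but in different clusters: rule order keeps them
        # in the both_conserved class
        pike = np.array([1.0, 8.0, 0.0, 5.0, 3.0, 2.0, 7.0, 1.0, 0.0, 4.0, 6.0, 2.0, 3.0])
        t = OrthologTriplet("a", "b", "p", pike, pike * 1.1, pike)
        call = classify_triplet(t, self._clusters(1, 2), CFG)
        assert call.category == "both_conserved"

    def test_neofunctionalized(self):
        x, base = profile_with_r(0.2)
        pike_fpkm = 2.0 ** (4 + base / 6.0) - 1.0
        redrawn_fpkm = 2.0 ** (4 + 2 * x) - 1.0
        t = OrthologTriplet("a", "b", "p", pike_fpkm, redrawn_fpkm, pike_fpkm)
        call = classify_triplet(t, self._clusters(1, 2), CFG)
        assert call.category == "neofunctionalized"
        assert call.status_a == "conserved" and call.status_b == "diverged"

    def test_subfunctionalized_partition(self, small_zero_noise_bundle):
        b = small_zero_noise_bundle
        row = b.truth[b.truth.fate == "subfunctionalized"].iloc[0]
        common = b.pike.tissues
        t = OrthologTriplet(
            "a", "b", "p",
            b.salmon.values.loc[row.gene_a, common].to_numpy(),
            b.salmon.values.loc[row.gene_b, common].to_numpy(),
            b.pike.values.loc[row.gene_pike].to_numpy(),
        )
        call = classify_triplet(t, self._clusters(1, 2), CFG)
        assert call.category == "subfunctionalized"
        assert call.r_sum == pytest.approx(1.0, abs=1e-9)

    def test_missing_cluster_label_raises(self):
        pike = np.array([1.0, 2.0, 3.0])
        t = OrthologTriplet("nope", "b", "p", pike, pike, pike)
        with pytest.raises(KeyError, match="nope"):
            classify_triplet(t, self._clusters(1, 1), CFG)


class TestTissueSpecificity:
    def test_uniform_zero(self):
        assert tissue_specificity(np.full(6, 3.0)) == 0.0

    def test_one_hot_one(self):
        x = np.zeros(6)
        x[2] = 9.0
        assert tissue_specificity(x) == 1.0

    def test_hand_value(self):
        assert tissue_specificity(np.array([4.0, 2.0, 2.0])) == pytest.approx(0.5)

    def test_all_zero_undefined(self):
        assert np.isnan(tissue_specificity(np.zeros(4)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4), min_size=2, max_size=15).filter(lambda x: max(x) > 0),
        st.floats(1e-3, 1e3),
    )
    def test_bounds_and_scale_invariance(self, profile, scale):
        x = np.asarray(profile)
        tau = tissue_specificity(x)
        assert 0.0 <= tau <= 1.0
        assert tissue_specificity(scale * x) == pytest.approx(tau, rel=1e-9)


class TestSpecificityClusterTest:
    def test_identical_multisets_p_one(self):
        c = ClusterAssignment(labels={"a": 1, "b": 1, "c": 2, "d": 2}, k=2)
        scores = {"a": 0.3, "b": 0.7, "c": 0.3, "d": 0.7}
        out = specificity_cluster_test(c, scores)
        assert out.p_value.tolist() == [1.0]

    def test_separated_clusters_exact_p(self):
        c = ClusterAssignment(labels={g: 1 for g in "abc"} | {g: 2 for g in "xyz"}, k=2)
        scores = {"a": 0.1, "b": 0.2, "c": 0.3, "x": 0.7, "y": 0.8, "z": 0.9}
        out = specificity_cluster_test(c, scores)
        # exact two-sided rank-sum p at n=m=3 with complete separation
        assert out.p_value.iloc[0] == pytest.approx(0.1)

    def test_single_shared_value_p_one(self):
        c = ClusterAssignment(labels={"a": 1, "b": 2}, k=2)
        out = specificity_cluster_test(c, {"a": 0.5, "b": 0.5})
        assert out.p_value.iloc[0] == 1.0

    def test_unscored_cluster_skipped(self):
        c = ClusterAssignment(labels={"a": 1, "b": 1, "c": 2}, k=2)
        with pytest.warns(UserWarning, match="skipped"):
            out = specificity_cluster_test(c, {"a": 0.1, "b": 0.2})
        assert out.empty
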
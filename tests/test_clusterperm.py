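"""Bin-level permutation tests, clustering, and the two-step procedure."""

import itertools

import numpy as np
import pytest
from scipy import stats

from trialwave import (
    BinTestResult,
    ClusterPermutationTest,
    binwise_permutation_test,
    cluster_permutation_test,
    form_clusters,
    report,
)
from trialwave.tft import TFTMap, frequency_grid


def scalar_maps(values, nbins=1):
    """Wrap scalar subject values into degenerate 1-frequency maps."""
    g = frequency_grid(8, f_max=1.0 / 8.0)
    out = []
    for v in values:
        p = np.full((8, 1), float(v))
        out.append(TFTMap(power=p, grid=g, coi_mask=np.zeros((8, 1), bool)))
    return out


def random_maps(rng, n, T=12, F=6):
    assert F <= T // 2
    g = frequency_grid(T, f_max=F / T)
    return [
        TFTMap(power=rng.gamma(2.0, 1.0, size=(T, F)), grid=g,
               coi_mask=np.zeros((T, F), bool))
        for _ in range(n)
    ]


def make_bin_result(t_map, sig_mask, alpha_bin=0.001):
    return BinTestResult(t_map=np.asarray(t_map, float),
                         p_map=np.where(sig_mask, alpha_bin / 2, 1.0),
                         sig_mask=np.asarray(sig_mask, bool),
                         alpha_bin=alpha_bin, n_shuffle=1000)


class TestBinwisePermutation:
    def test_exact_enumeration_matches_oracle(self):
        """With <= n_shuffle relabelings the p equals the exhaustive one."""
        res = binwise_permutation_test(scalar_maps([1, 2, 3]),
                                       scalar_maps([4, 5, 6]),
                                       n_shuffle=100, seed=0)
        assert res.exact
        # oracle: enumerate all C(6,3)=20 assignments
        vals = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        t_obs = stats.ttest_ind(vals[:3], vals[3:], equal_var=False).statistic
        count = 0
        for combo in itertools.combinations(range(6), 3):
            ga = vals[list(combo)]
            gb = np.delete(vals, list(combo))
            t = stats.ttest_ind(ga, gb, equal_var=False).statistic
            count += abs(t) >= abs(t_obs) - 1e-12
        assert res.p_map[0, 0] == pytest.approx(count / 20)

    def test_identical_groups_give_t_zero(self):
        rng = np.random.default_rng(3)
        maps = random_maps(rng, 5)
        res = binwise_permutation_test(maps, maps, n_shuffle=200, seed=1)
        np.testing.assert_allclose(res.t_map, 0.0, atol=1e-12)
        assert not res.sig_mask.any()

    def test_t_matches_scipy_welch(self):
        rng = np.random.default_rng(4)
        ma, mb = random_maps(rng, 7), random_maps(rng, 5)
        res = binwise_permutation_test(ma, mb, n_shuffle=50, seed=0)
        A = np.stack([m.power for m in ma])
        B = np.stack([m.power for m in mb])
        expected = stats.ttest_ind(A, B, axis=0, equal_var=False).statistic
        np.testing.assert_allclose(res.t_map, expected, rtol=1e-10)

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(5)
        ma, mb = random_maps(rng, 8), random_maps(rng, 8)
        res = binwise_permutation_test(ma, mb, design="paired",
                                       n_shuffle=100, seed=0)
        A = np.stack([m.power for m in ma])
        B = np.stack([m.power for m in mb])
        expected = stats.ttest_rel(A, B, axis=0).statistic
        np.testing.assert_allclose(res.t_map, expected, rtol=1e-10)

    def test_degenerate_bins_get_p_one(self):
        res = binwise_permutation_test(scalar_maps([2, 2, 2]),
                                       scalar_maps([2, 2, 2]),
                                       n_shuffle=50, seed=0)
        assert np.all(res.p_map == 1.0)
        assert np.all(res.t_map == 0.0)

    def test_p_values_bounded_below(self):
        rng = np.random.default_rng(6)
        ma, mb = random_maps(rng, 6), random_maps(rng, 6)
        res = binwise_permutation_test(ma, mb, n_shuffle=99, seed=2)
        lo = 1.0 / (99 + 1) if not res.exact else 1.0 / 924
        assert np.all(res.p_map >= lo - 1e-15)
        assert np.all(res.p_map <= 1.0)

    def test_null_bin_rejection_rate_is_calibrated(self):
        """Identically-generated groups reject ~alpha_bin of bins."""
        rng = np.random.default_rng(7)
        rates = []
        for rep in range(20):
            ma = random_maps(rng, 10, T=20, F=10)
            mb = random_maps(rng, 10, T=20, F=10)
            res = binwise_permutation_test(ma, mb, n_shuffle=199,
                                           alpha_bin=0.05, seed=rep)
            rates.append(res.sig_mask.mean())
        # 20 reps x 120 bins: mean rejection within a generous band of 0.05
        assert 0.02 < np.mean(rates) < 0.09

    def test_unequal_paired_lists_rejected(self):
        with pytest.raises(ValueError):
            binwise_permutation_test(scalar_maps([1, 2, 3]),
                                     scalar_maps([4, 5]),
                                     design="paired", n_shuffle=10, seed=0)


class TestFormClusters:
    def test_empty_mask_gives_no_clusters(self):
        res = make_bin_result(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert form_clusters(res) == []

    def test_separated_blocks_form_two_clusters(self):
        sig = np.zeros((5, 5), bool)
        sig[0:2, 0:2] = True
        sig[3:5, 3:5] = True
        res = make_bin_result(np.ones((5, 5)), sig)
        clusters = form_clusters(res)
        assert len(clusters) == 2
        assert sorted(c.n_bins for c in clusters) == [4, 4]
        assert all(c.mass == pytest.approx(c.n_bins) for c in clusters)

    def test_L_shape_is_one_cluster_under_4_connectivity(self):
        sig = np.zeros((4, 4), bool)
        sig[0, 0:3] = True
        sig[1:3, 0] = True
        res = make_bin_result(np.full((4, 4), 2.0), sig)
        clusters = form_clusters(res, connectivity=4)
        assert len(clusters) == 1
        assert clusters[0].n_bins == 5
        assert clusters[0].mass == pytest.approx(10.0)

    def test_diagonal_touch_needs_8_connectivity(self):
        sig = np.zeros((4, 4), bool)
        sig[0, 0] = sig[1, 1] = True
        res = make_bin_result(np.ones((4, 4)), sig)
        assert len(form_clusters(res, connectivity=4)) == 2
        assert len(form_clusters(res, connectivity=8)) == 1

    def test_opposite_signs_split_even_when_adjacent(self):
        sig = np.zeros((3, 3), bool)
        sig[1, :] = True
        t = np.zeros((3, 3))
        t[1, 0] = t[1, 1] = 3.0
        t[1, 2] = -3.0
        res = make_bin_result(t, sig)
        clusters = form_clusters(res)
        signs = sorted(c.sign for c in clusters)
        assert len(clusters) == 2 and signs == [-1, 1]
        masses = sorted(c.mass for c in clusters)
        assert masses == pytest.approx([-3.0, 6.0])


class TestClusterPermutation:
    def test_identical_groups_give_zero_clusters(self):
        rng = np.random.default_rng(9)
        maps = random_maps(rng, 6)
        res = cluster_permutation_test(maps, maps, n_shuffle=100, seed=0)
        assert res.n_significant == 0
        assert res.trials_covered_fraction == 0.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        ma, mb = random_maps(rng, 6), random_maps(rng, 6)
        r1 = cluster_permutation_test(ma, mb, n_shuffle=150, alpha_bin=0.05,
                                      seed=11)
        r2 = cluster_permutation_test(ma, mb, n_shuffle=150, alpha_bin=0.05,
                                      seed=11)
        np.testing.assert_array_equal(r1.t_map, r2.t_map)
        np.testing.assert_array_equal(r1.p_map, r2.p_map)
        assert len(r1.clusters) == len(r2.clusters)
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1.p_value == c2.p_value
            assert np.array_equal(c1.bins, c2.bins)
        np.testing.assert_array_equal(r1.null_max_masses, r2.null_max_masses)

    def test_label_symmetry_in_exhaustive_mode(self):
        """Swapping groups negates t and preserves p and significance."""
        rng = np.random.default_rng(12)
        ma, mb = random_maps(rng, 4, T=10, F=4), random_maps(rng, 4, T=10, F=4)
        # C(8,4)=70 relabelings <= n_shuffle -> exhaustive, hence symmetric
        r_ab = cluster_permutation_test(ma, mb, n_shuffle=100, alpha_bin=0.1,
                                        seed=0)
        r_ba = cluster_permutation_test(mb, ma, n_shuffle=100, alpha_bin=0.1,
                                        seed=0)
        assert r_ab.exact and r_ba.exact
        np.testing.assert_allclose(r_ba.t_map, -r_ab.t_map, rtol=1e-10)
        np.testing.assert_allclose(r_ba.p_map, r_ab.p_map, rtol=1e-12)
        assert len(r_ab.clusters) == len(r_ba.clusters)
        for c1, c2 in zip(r_ab.clusters, r_ba.clusters):
            assert c1.mass == pytest.approx(-c2.mass)
            assert c1.p_value == pytest.approx(c2.p_value)

    def test_lowering_alpha_bin_never_adds_significant_bins(self):
        rng = np.random.default_rng(13)
        ma, mb = random_maps(rng, 6), random_maps(rng, 6)
        counts = []
        for alpha in (0.2, 0.05, 0.01):
            res = binwise_permutation_test(ma, mb, n_shuffle=199,
                                           alpha_bin=alpha, seed=3)
            counts.append(int(res.sig_mask.sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_injected_difference_is_detected_and_localized(self):
        """A strong group difference in a bin block yields a cluster there."""
        rng = np.random.default_rng(14)
        T, F = 16, 8
        g = frequency_grid(T, f_max=F / T)
        def make(shifted):
            p = rng.gamma(2.0, 1.0, size=(T, F))
            if shifted:
                p[4:9, 2:6] += 12.0
            return TFTMap(power=p, grid=g, coi_mask=np.zeros((T, F), bool))
        ma = [make(True) for _ in range(10)]
        mb = [make(False) for _ in range(10)]
        res = cluster_permutation_test(ma, mb, n_shuffle=300, alpha_bin=0.01,
                                       seed=5)
        assert res.n_significant >= 1
        top = res.significant_clusters[0]
        t0, t1 = top.trial_range
        assert t0 >= 3 and t1 <= 10
        assert top.sign == 1
        assert 0 < res.trials_covered_fraction <= 1

    def test_cluster_p_values_bounded(self, null_cohort_maps):
        ma, mb = null_cohort_maps
        res = cluster_permutation_test(ma, mb, n_shuffle=99, alpha_bin=0.05,
                                       seed=21)
        for c in res.clusters:
            assert 1.0 / 100 <= c.p_value <= 1.0

    def test_model_results_roundtrip_and_summary(self, null_cohort_maps):
        ma, mb = null_cohort_maps
        model = ClusterPermutationTest(ma, mb)
        res = model.fit(n_shuffle=99, alpha_bin=0.05, seed=1)
        text = res.summary()
        assert "significant clusters" in text
        d = res.to_dict()
        assert d["n_clusters"] == len(res.clusters)
        rep = report(res)
        assert rep["n_clusters"] == len(res.clusters)
        assert 0.0 <= rep["trials_covered_fraction"] <= 1.0

    def test_coverage_fraction_definition(self):
        """One cluster over trials 10-19 of T=100 covers 10% of trials."""
        sig = np.zeros((100, 5), bool)
        sig[10:20, :] = True
        res = make_bin_result(np.ones((100, 5)), sig)
        clusters = form_clusters(res)
        assert len(clusters) == 1
        trials = clusters[0].trials()
        assert trials.size == 10
        assert trials.min() == 10 and trials.max() == 19

    def test_paired_pure_shift_of_maps_is_null(self):
        """Identical maps pre/post yield no clusters in a paired design."""
        rng = np.random.default_rng(15)
        ma = random_maps(rng, 6)
        res = cluster_permutation_test(ma, ma, design="paired",
                                       n_shuffle=64, seed=0)
        assert res.n_significant == 0

    def test_alpha_validation(self, null_cohort_maps):
        ma, mb = null_cohort_maps
        with pytest.raises(ValueError):
            cluster_permutation_test(ma, mb, n_shuffle=10, alpha_bin=1.5, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(scalar_maps([1.0]), scalar_maps([2, 3]),
                                     n_shuffle=10, seed=0)
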
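"""z-normalization, bimodality, binarization, labeling and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nafld_grn.states import (
    DegenerateDistributionError,
    all_labels,
    bimodality_coefficient,
    binarize,
    calls_to_labels,
    cluster_quadrant_labels,
    hierarchical_clusters,
    state_frequency_distribution,
    z_normalize,
)


class TestZNormalize:
    def test_two_point_sample(self):
        zn = z_normalize(np.array([0.0, 2.0]))
        np.testing.assert_allclose(zn.z, [-1.0, 1.0])  # population sd

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, 500)
        z1 = z_normalize(x).z
        z2 = z_normalize(z1).z
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_output_standardized(self, values):
        x = np.asarray(values)
        if x.std() == 0:
            return
        zn = z_normalize(x)
        assert zn.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert zn.z.std() == pytest.approx(1.0, rel=1e-9)

    def test_constant_pool_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            z_normalize(np.full(10, 3.0))


class TestBimodalityCoefficient:
    def test_uniform_limit(self):
        rng = np.random.default_rng(1)
        b = bimodality_coefficient(rng.uniform(0, 1, 1_000_000))
        assert b.coefficient == pytest.approx(5.0 / 9.0, abs=0.01)

    def test_normal_limit(self):
        rng = np.random.default_rng(2)
        b = bimodality_coefficient(rng.normal(0, 1, 500_000))
        assert b.coefficient == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_symmetric_two_point_sample(self):
        # skewness 0, excess kurtosis -> -2, so b -> 1 as n grows
        x = np.array([-1.0, 1.0] * 5000)
        b = bimodality_coefficient(x)
        assert b.skewness == pytest.approx(0.0, abs=1e-12)
        assert b.excess_kurtosis == pytest.approx(-2.0, abs=1e-9)
        assert b.coefficient == pytest.approx(1.0, abs=1e-3)

    def test_matches_independent_moment_computation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.normal(size=rng.integers(10, 200)) ** rng.integers(1, 3)
            n = x.size
            m = x - x.mean()
            m2 = np.mean(m**2)
            g = np.mean(m**3) / m2**1.5
            k = np.mean(m**4) / m2**2 - 3.0
            expected = (g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
            got = bimodality_coefficient(x)
            assert got.coefficient == pytest.approx(expected, rel=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            bimodality_coefficient(np.array([1.0, 2.0, 3.0]))


class TestBinarize:
    def _mixture(self, rng, n=4000, sep=2.0, sd=0.5):
        labels = rng.random(n) < 0.5
        return np.where(labels, sep, -sep) + rng.normal(0, sd, n), labels

    def test_balanced_mixture_threshold_and_calls(self):
        rng = np.random.default_rng(4)
        x, labels = self._mixture(rng)
        res = binarize(x[:, None], ("G",))
        assert -1.0 < res.thresholds[0] < 1.0
        agreement = np.mean(res.calls[:, 0] == labels)
        assert agreement >= 0.99

    def test_bimodal_node_yields_both_calls(self):
        rng = np.random.default_rng(5)
        x, _ = self._mixture(rng)
        res = binarize(x[:, None], ("G",))
        assert res.calls[:, 0].any() and (~res.calls[:, 0]).any()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x, _ = self._mixture(rng)
        a = binarize(x[:, None], ("G",)).calls
        b = binarize((3.5 * x + 40.0)[:, None], ("G",)).calls
        np.testing.assert_array_equal(a, b)

    def test_unimodal_falls_back_to_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 2000)
        with pytest.warns(UserWarning, match="falling back"):
            res = binarize(x[:, None], ("G",))
        assert res.thresholds[0] == 0.0


class TestLabelsAndFrequencies:
    def test_all_labels_count(self):
        assert len(all_labels(4)) == 16
        assert len(set(all_labels(4))) == 16
        assert all_labels(2) == ["HH", "HL", "LH", "LL"]

    def test_frequency_distribution_sums_to_one(self):
        labels = np.array(["HHLL", "LLHH", "HHLL", "HHHH"])
        freq = state_frequency_distribution(labels, 4)
        assert freq.sum() == pytest.approx(1.0)
        assert freq["HHLL"] == pytest.approx(0.5)
        assert len(freq) == 16

    def test_calls_to_labels_subset(self):
        calls = np.array([[True, False, True, False]])
        assert calls_to_labels(calls)[0] == "HLHL"
        assert calls_to_labels(calls, [0, 2])[0] == "HH"


class TestWildtypeEnsembleClassification:
    def test_pair_labels_hl_lh_most_abundant(self, wt_phases):
        counts = (
            __import__("pandas").Series(wt_phases.pair_labels).value_counts()
        )
        assert set(counts.index[:2]) == {"HL", "LH"}

    def test_phase_size_matches_state_count_for_distinct_labels(self, wt_phases):
        for mid, phase in wt_phases.phases.items():
            assert len(phase) <= wt_phases.state_counts[mid]

    def test_most_frequent_bistable_phase_is_hl_lh(self, wt_phases):
        tally = wt_phases.phase_tally(n_states=2)
        assert tally.index[0] == ("HL", "LH")

    def test_at_most_six_bistable_and_four_tristable_phases(self, wt_phases):
        assert len(wt_phases.phase_tally(n_states=2)) <= 6
        assert len(wt_phases.phase_tally(n_states=3)) <= 4

    def test_frequency_distribution_normalized(self, wt_phases):
        assert wt_phases.frequency.sum() == pytest.approx(1.0)

    def test_correlation_sign_structure(self, wt_ensemble):
        # pooled steady states: hepatic pair up together, adipocytic pair up
        # together, the two programs anti-correlated
        levels, _ = wt_ensemble.pooled_states()
        nodes = list(wt_ensemble.network.nodes)
        def rho(a, b):
            return stats.spearmanr(levels[:, nodes.index(a)], levels[:, nodes.index(b)])[0]
        assert rho("HNF4A", "PPARG") < 0
        assert rho("HNF4A", "HNF1A") > 0
        assert rho("PPARG", "SREBF1") > 0
        assert rho("HNF4A", "SREBF1") < 0
        assert rho("HNF1A", "PPARG") < 0


class TestHierarchicalClusters:
    def test_four_blobs_recovered(self):
        rng = np.random.default_rng(8)
        centers = np.array([[2, 2], [2, -2], [-2, 2], [-2, -2]], dtype=float)
        truth = np.repeat(np.arange(4), 100)
        X = centers[truth] + rng.normal(0, 0.3, (400, 2))
        got = hierarchical_clusters(X, k=4)
        # perfect recovery up to label permutation
        for c in range(4):
            members = got[truth == c]
            assert np.all(members == members[0])
        quad = cluster_quadrant_labels(X, got)
        assert set(quad.values()) == {"HH", "HL", "LH", "LL"}

    def test_k_one_single_cluster(self):
        X = np.random.default_rng(9).normal(size=(50, 2))
        assert np.all(hierarchical_clusters(X, k=1) == 0)

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clusters(np.zeros((3, 2)), k=5)
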
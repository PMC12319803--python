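import numpy as np
import pytest
import scipy.special
import scipy.stats
from hypothesis import given, settings, strategies as st

from tacsalpha import (
    ClusterTestSpec,
    block_contrast,
    cluster_permutation_test,
    delta_power,
    grid_adjacency,
    grid_layout,
    pool_blocks,
    rank_sum_test,
    region_split_test,
)
from tacsalpha.cluster_stats import DeltaPowerMap

from oracles import exhaustive_cluster_p, pooled_t, rank_sum_u


def chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestDeltaPower:
    def test_identical_samples_give_zero(self):
        post = np.array([1.0, 2.0, 3.0])[:, None]
        base = np.array([1.0, 2.0, 3.0])[:, None]
        assert delta_power(post, base).values[0] == 0.0

    def test_textbook_example(self):
        """baseline {1,2,3,4}, post {3,4,5,6}: t = 2/(1.29099*sqrt(0.5))."""
        post = np.array([3.0, 4.0, 5.0, 6.0])[:, None]
        base = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        t = delta_power(post, base).values[0]
        assert t == pytest.approx(2.0 / (1.2909944 * np.sqrt(0.5)), rel=1e-6)
        assert t == pytest.approx(pooled_t(post[:, 0], base[:, 0]))

    def test_matches_scipy_on_random_fixtures(self, rng):
        """Vectorised pooled t equals scipy.stats.ttest_ind, 100 fixtures,
        max abs diff < 1e-10."""
        worst = 0.0
        for _ in range(100):
            n1, n2 = rng.integers(3, 25, size=2)
            post = rng.standard_normal((n1, 4, 6))
            base = rng.standard_normal((n2, 4, 6))
            mine = delta_power(post, base).values
            ref = scipy.stats.ttest_ind(
                post, base.mean(axis=-1)[..., None], axis=0, equal_var=True
            ).statistic
            worst = max(worst, np.abs(mine - ref).max())
        assert worst < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        post = rng.random((5, 3)) + 0.5
        base = rng.random((6, 3)) + 0.5
        a = delta_power(post, base).values
        b = delta_power(c * post, c * base).values
        assert np.allclose(a, b, rtol=1e-9)

    def test_baseline_time_axis_averaged_first(self, rng):
        post = rng.standard_normal((5, 2, 4))
        base_t = rng.standard_normal((6, 2, 3))
        a = delta_power(post, base_t).values
        b = delta_power(post, base_t.mean(axis=-1)).values
        assert np.allclose(a, b)

    def test_degenerate_variance_errors(self):
        post = np.array([2.0, 2.0, 2.0])[:, None]
        base = np.array([1.0, 1.0, 1.0])[:, None]
        with pytest.raises(ValueError, match="degenerate variance"):
            delta_power(post, base)

    def test_welch_variant_available(self, rng):
        post = rng.standard_normal((8, 3, 1)) * 3
        base = rng.standard_normal((12, 3))
        mine = delta_power(post, base, variance="welch").values[..., 0]
        ref = scipy.stats.ttest_ind(post[..., 0], base, axis=0,
                                    equal_var=False).statistic
        assert np.allclose(mine, ref)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            delta_power(np.ones((1, 2)), np.ones((5, 2)))


class TestPoolBlocks:
    def _map(self, vals):
        return DeltaPowerMap(values=np.asarray(vals, float))

    def test_identical_blocks_idempotent(self):
        m = self._map([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(pool_blocks(m, m).values, m.values)

    def test_opposite_blocks_cancel(self):
        a = self._map([1.0, -2.0])
        b = self._map([-1.0, 2.0])
        assert np.array_equal(pool_blocks(a, b).values, [0.0, 0.0])

    def test_average_of_2_and_4_is_3(self):
        assert np.all(pool_blocks(self._map([2.0]), self._map([4.0])).values
                      == 3.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pool_blocks(self._map([1.0, 2.0]), self._map([1.0]))

    def test_time_average_variant(self):
        a = self._map([[1.0, 3.0]])
        pooled = pool_blocks(a, a, time_average=True)
        assert np.array_equal(pooled.values, [2.0])


class TestClusterPermutation:
    def test_identical_conditions_no_clusters(self, rng):
        maps = rng.standard_normal((6, 9))
        spec = ClusterTestSpec(n_permutations=100, seed=0)
        res = cluster_permutation_test(maps, maps.copy(), spec,
                                       grid_layout(3, 3).adjacency)
        assert res.clusters == []

    def test_four_participants_match_exhaustive_enumeration(self):
        """Hand-built 3-unit-chain maps: p equals the 16-assignment
        enumeration computed by an independent networkx oracle."""
        tacs = np.array([
            [2.0, 2.2, 0.1],
            [1.5, 1.8, -0.2],
            [2.4, 2.1, 0.0],
            [1.9, 2.6, 0.3],
        ])
        control = np.array([
            [0.2, 0.1, 0.0],
            [-0.1, 0.3, 0.1],
            [0.4, 0.2, -0.2],
            [0.0, -0.1, 0.2],
        ])
        adj = chain_adjacency(3)
        spec = ClusterTestSpec(n_permutations=1000, seed=3)
        res = cluster_permutation_test(tacs, control, spec, adj)
        assert res.exhaustive
        oracle = exhaustive_cluster_p(tacs, control, adj)
        assert len(res.clusters) == len(oracle) == 1
        members, sum_t, p = oracle[0]
        assert list(res.clusters[0].members) == members
        assert res.clusters[0].sum_t == pytest.approx(sum_t)
        assert res.clusters[0].p == p

    def test_monte_carlo_agrees_with_enumeration_within_binomial_error(
        self, rng
    ):
        """With 2^n just above n_permutations the Monte-Carlo path runs;
        its p must sit within binomial error of the exhaustive value."""
        n = 11  # 2^11 = 2048 > 1500 permutations -> Monte-Carlo
        tacs = rng.standard_normal((n, 4)) + np.array([2.0, 2.1, 1.9, 0.0])
        control = rng.standard_normal((n, 4))
        adj = chain_adjacency(4)
        spec = ClusterTestSpec(n_permutations=1500, seed=7)
        res = cluster_permutation_test(tacs, control, spec, adj)
        assert not res.exhaustive
        oracle = exhaustive_cluster_p(tacs, control, adj)
        assert len(res.clusters) == len(oracle) >= 1
        for cl, (members, sum_t, p_exact) in zip(res.clusters, oracle):
            se = np.sqrt(p_exact * (1 - p_exact) / spec.n_permutations)
            assert abs(cl.p - p_exact) < max(4 * se, 2 / spec.n_permutations)

    def test_label_exchange_flips_sign_keeps_p(self, rng):
        tacs = rng.standard_normal((8, 9)) + 1.2
        control = rng.standard_normal((8, 9))
        adj = grid_layout(3, 3).adjacency
        spec = ClusterTestSpec(n_permutations=300, seed=5)
        a = cluster_permutation_test(tacs, control, spec, adj)
        b = cluster_permutation_test(control, tacs, spec, adj)
        assert len(a.clusters) == len(b.clusters) >= 1
        for ca, cb in zip(a.clusters, b.clusters):
            assert ca.sign == -cb.sign
            assert ca.sum_t == pytest.approx(-cb.sum_t)
            assert ca.p == cb.p
        assert np.allclose(a.t_obs, -b.t_obs)

    def test_isolated_suprathreshold_unit_is_not_a_cluster(self):
        """The minimum-two-neighbours rule: one extreme isolated unit on an
        otherwise flat map forms no cluster."""
        tacs = np.zeros((6, 5))
        tacs[:, 2] = [5.0, 5.5, 4.8, 5.1, 5.3, 4.9]
        control = np.zeros((6, 5))
        adj = np.zeros((5, 5), dtype=bool)  # unit 2 has no neighbours
        adj[0, 1] = adj[1, 0] = adj[3, 4] = adj[4, 3] = True
        tacs += np.random.default_rng(0).normal(0, 1e-3, tacs.shape)
        spec = ClusterTestSpec(n_permutations=100, seed=1)
        res = cluster_permutation_test(tacs, control, spec, adj)
        assert res.clusters == []

    def test_empty_adjacency_rejected(self, rng):
        maps = rng.standard_normal((4, 3))
        spec = ClusterTestSpec(n_permutations=10, seed=0)
        with pytest.raises(ValueError, match="empty adjacency"):
            cluster_permutation_test(maps, maps, spec,
                                     np.zeros((3, 3), dtype=bool))


class TestRegionSplit:
    def test_all_somatosensory_labels_error_on_frontal(self, rng):
        layout = grid_layout(2, 2, somatosensory=(slice(0, 2), slice(0, 2)))
        maps = rng.standard_normal((5, 4, 3, 4))
        spec = ClusterTestSpec(n_permutations=50, seed=0)
        with pytest.raises(ValueError, match="frontal"):
            region_split_test(maps, rng.standard_normal(maps.shape),
                              np.arange(4), layout, spec)

    def test_identical_halves_identical_statistics(self, rng):
        layout = grid_layout(2, 2, somatosensory=(slice(0, 1), slice(0, 2)),
                             frontal=(slice(1, 2), slice(0, 2)))
        half = rng.standard_normal((6, 2, 4, 5))
        tacs = np.concatenate([half, half], axis=1) + 0.8
        control_half = rng.standard_normal((6, 2, 4, 5))
        control = np.concatenate([control_half, control_half], axis=1)
        spec = ClusterTestSpec(n_permutations=200, seed=2)
        res = region_split_test(tacs, control, np.arange(4), layout, spec)
        assert np.allclose(res["somatosensory"].t_obs, res["frontal"].t_obs)
        assert [c.p for c in res["somatosensory"].clusters] \
            == [c.p for c in res["frontal"].clusters]


class TestBlockContrast:
    def test_identical_blocks_maximal_p(self, rng):
        maps = {"train10": rng.standard_normal((6, 5)) + 1.0}
        maps["train30"] = maps["train10"].copy()
        ctrl = {"train10": rng.standard_normal((6, 5))}
        ctrl["train30"] = ctrl["train10"].copy()
        res = block_contrast(maps, ctrl, np.arange(5))
        assert res.p == 1.0

    def test_complete_separation_minimal_p(self):
        x = np.arange(1.0, 6.0)
        y = x + 100.0
        u, p = rank_sum_test(y, x)
        assert u == 25.0  # all pairwise wins
        exact_min = 2.0 / scipy.special.comb(10, 5)  # two-sided, 2/252
        assert p == pytest.approx(exact_min, rel=1e-6)

    def test_statistic_matches_closed_form_u(self, rng):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        u, _ = rank_sum_test(x, y)
        assert u == rank_sum_u(x, y)

    def test_cluster_too_small_rejected(self, rng):
        maps = {"a": rng.standard_normal((4, 3)),
                "b": rng.standard_normal((4, 3))}
        with pytest.raises(ValueError, match="at least 2"):
            block_contrast(maps, maps, np.array([1]))
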
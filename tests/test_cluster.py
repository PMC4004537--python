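import itertools

import numpy as np
import pytest
import scipy.stats

import betabind as bb
from betabind.cluster import _max_cluster_mass, _adjacency_pairs


def brute_force_clusters(t_map, mask, adjacency):
    """Oracle: breadth-first connected components over masked samples,
    sign-homogeneous, time adjacency = consecutive samples."""
    n_s, n_t = t_map.shape
    seen = set()
    clusters = []
    for s0 in range(n_s):
        for t0 in range(n_t):
            if not mask[s0, t0] or (s0, t0) in seen:
                continue
            sign = np.sign(t_map[s0, t0])
            comp, stack = [], [(s0, t0)]
            seen.add((s0, t0))
            while stack:
                s, t = stack.pop()
                comp.append((s, t))
                neigh = [(s, t - 1), (s, t + 1)] + [
                    (s2, t) for s2 in range(n_s) if adjacency[s, s2]]
                for s2, t2 in neigh:
                    if (0 <= t2 < n_t and mask[s2, t2]
                            and (s2, t2) not in seen
                            and np.sign(t_map[s2, t2]) == sign):
                        seen.add((s2, t2))
                        stack.append((s2, t2))
            clusters.append((frozenset(comp),
                             sum(t_map[s, t] for s, t in comp)))
    return clusters


class TestSamplewiseStat:
    def test_identical_groups_give_zero(self):
        x = np.random.default_rng(0).standard_normal((10, 4, 20))
        t, mask, _ = bb.samplewise_stat(x, x.copy())
        assert np.all(t == 0)
        assert not mask.any()

    def test_zero_variance_sample_warns_and_is_subthreshold(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((8, 1, 5))
        b = rng.standard_normal((8, 1, 5))
        a[:, 0, 2] = b[:, 0, 2] = 1.0  # constant sample in both groups
        with pytest.warns(UserWarning, match="zero-variance"):
            t, mask, _ = bb.samplewise_stat(a, b)
        assert t[0, 2] == 0 and not mask[0, 2]

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((12, 3, 7))
        b = rng.standard_normal((15, 3, 7)) + 0.3
        t, _, tcrit = bb.samplewise_stat(a, b, "independent")
        ref = scipy.stats.ttest_ind(a, b, axis=0)
        assert np.allclose(t, ref.statistic)
        assert tcrit == pytest.approx(scipy.stats.t.ppf(0.975, 25))
        tp, _, _ = bb.samplewise_stat(a, a + b[:12], "paired")
        refp = scipy.stats.ttest_rel(a, a + b[:12], axis=0)
        assert np.allclose(tp, refp.statistic)

    def test_white_noise_mask_rate_is_nominal(self):
        rng = np.random.default_rng(2)
        fracs = [bb.samplewise_stat(rng.standard_normal((20, 5, 40)),
                                    rng.standard_normal((20, 5, 40)))[1].mean()
                 for _ in range(50)]
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_planted_effect_localizes(self, layout20):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((40, 20, 50))
        b = rng.standard_normal((40, 20, 50))
        cp = layout20.region_sensors("central-parietal")
        a[:, cp[:, None], np.arange(25, 50)] += 1.2
        _, mask, _ = bb.samplewise_stat(a, b)
        inside = mask[cp][:, 25:].mean()
        outside_mask = mask.copy()
        outside_mask[cp[:, None], np.arange(25, 50)] = False
        assert inside > 0.8
        assert outside_mask.mean() < 0.1


class TestFormClusters:
    @staticmethod
    def _toy():
        t_map = np.zeros((3, 4))
        adjacency = np.zeros((3, 3), bool)
        adjacency[0, 1] = adjacency[1, 0] = True
        t_map[0, 0] = t_map[0, 1] = t_map[1, 1] = 3.0
        t_map[2, 3] = 3.0
        return t_map, adjacency

    def test_hand_built_toy_masses(self):
        t_map, adjacency = self._toy()
        clusters = bb.form_clusters(t_map, np.abs(t_map) > 2, adjacency)
        assert [c.sum_t for c in clusters] == [9.0, 3.0]

    def test_bridged_toy_merges(self):
        t_map, adjacency = self._toy()
        adjacency[1, 2] = adjacency[2, 1] = True
        t_map[1, 3] = 3.0
        clusters = bb.form_clusters(t_map, np.abs(t_map) > 2, adjacency)
        # (1,3)-(2,3) joins spatially but is not time-adjacent to (1,1)
        assert sorted(c.sum_t for c in clusters) == [6.0, 9.0]
        t_map[1, 2] = 3.0  # bridge sample time-connects (1,1)-(1,2)-(1,3)
        clusters = bb.form_clusters(t_map, np.abs(t_map) > 2, adjacency)
        assert len(clusters) == 1 and clusters[0].sum_t == 18.0

    def test_opposite_signs_never_merge(self):
        t_map = np.array([[3.0, -3.0, 3.0]])
        clusters = bb.form_clusters(t_map, np.abs(t_map) > 2,
                                    np.zeros((1, 1), bool))
        assert sorted(c.sum_t for c in clusters) == [-3.0, 3.0, 3.0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_s, n_t = 5, 6
        adjacency = rng.random((n_s, n_s)) < 0.4
        adjacency = adjacency | adjacency.T
        np.fill_diagonal(adjacency, False)
        t_map = rng.standard_normal((n_s, n_t)) * 3
        mask = np.abs(t_map) > 2
        ours = {(frozenset(c.members()), round(c.sum_t, 9))
                for c in bb.form_clusters(t_map, mask, adjacency)}
        oracle = {(m, round(s, 9)) for m, s in
                  brute_force_clusters(t_map, mask, adjacency)}
        assert ours == oracle

    def test_deterministic_ordering(self):
        t_map = np.array([[3.0, 0.0, 3.0]])
        clusters = bb.form_clusters(t_map, np.abs(t_map) > 2,
                                    np.zeros((1, 1), bool))
        assert clusters[0].samples.min() == 0  # tie broken by first sample


class TestClusterTest:
    def test_exhaustive_paired_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((4, 2, 3))
        b = rng.standard_normal((4, 2, 3))
        adjacency = np.ones((2, 2), bool)
        np.fill_diagonal(adjacency, False)
        with pytest.warns(UserWarning, match="exhaustively"):
            res = bb.cluster_test(a, b, adjacency, design="paired",
                                  n_permutations=100, seed=0)
        assert res.n_permutations == 16
        for c in res.clusters:
            assert (17 * c.p) == pytest.approx(round(17 * c.p))

    def test_permutation_p_matches_full_enumeration_oracle(self):
        # independent design, 4+3 observations -> C(7,4)=35 relabelings
        rng = np.random.default_rng(5)
        a = rng.standard_normal((4, 2, 4)) + 1.0
        b = rng.standard_normal((3, 2, 4))
        adjacency = np.ones((2, 2), bool)
        np.fill_diagonal(adjacency, False)
        with pytest.warns(UserWarning, match="exhaustively"):
            res = bb.cluster_test(a, b, adjacency, n_permutations=100, seed=0)
        pooled = np.concatenate([a, b])
        iu, ju = _adjacency_pairs(adjacency)
        null = []
        for idx in itertools.combinations(range(7), 4):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(7) if i not in idx]]
            t, _, tcrit = bb.samplewise_stat(ga, gb)
            null.append(_max_cluster_mass(t, tcrit, iu, ju))
        null = np.asarray(null)
        for c in res.clusters:
            expect = (1 + (null >= abs(c.sum_t)).sum()) / (1 + 35)
            assert c.p == pytest.approx(expect)

    def test_affine_rescaling_leaves_p_unchanged(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((15, 4, 10)) + 0.8
        b = rng.standard_normal((15, 4, 10))
        adjacency = np.zeros((4, 4), bool)
        adjacency[0, 1] = adjacency[1, 0] = adjacency[2, 3] = adjacency[3, 2] = True
        r1 = bb.cluster_test(a, b, adjacency, n_permutations=200, seed=3)
        r2 = bb.cluster_test(5.0 * a + 2.0, 5.0 * b + 2.0, adjacency,
                             n_permutations=200, seed=3)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
        assert [c.sum_t for c in r1.clusters] == pytest.approx(
            [c.sum_t for c in r2.clusters])

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((20, 3, 12)) + 0.5
        b = rng.standard_normal((20, 3, 12))
        adjacency = np.ones((3, 3), bool)
        np.fill_diagonal(adjacency, False)
        r1 = bb.cluster_test(a, b, adjacency, n_permutations=150, seed=9)
        r2 = bb.cluster_test(a, b, adjacency, n_permutations=150, seed=9)
        assert np.array_equal(r1.null_max, r2.null_max)

    def test_effect_size_monotonicity(self):
        # median max-cluster mass never decreases with the planted effect
        rng = np.random.default_rng(8)
        adjacency = np.ones((4, 4), bool)
        np.fill_diagonal(adjacency, False)
        med = []
        for d in (0.0, 0.5, 1.0, 1.5):
            masses = []
            for _ in range(25):
                a = rng.standard_normal((20, 4, 15))
                b = rng.standard_normal((20, 4, 15))
                a[:, :2, 5:] += d
                res = bb.cluster_test(a, b, adjacency, n_permutations=100,
                                      seed=1)
                masses.append(max((abs(c.sum_t) for c in res.clusters),
                                  default=0.0))
            med.append(np.median(masses))
        assert all(m2 >= m1 for m1, m2 in zip(med, med[1:]))

    def test_estimator_interface(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 3, 10))
        y = np.r_[np.zeros(15), np.ones(15)]
        X[y == 0, 0, 5:] += 1.5
        adjacency = np.zeros((3, 3), bool)
        est = bb.ClusterPermutationTest(adjacency=adjacency,
                                        n_permutations=200, random_state=0)
        est.fit(X, y)
        assert est.t_obs_.shape == (3, 10)
        assert est.null_max_.shape == (200,)
        assert est.get_params()["n_permutations"] == 200
        assert min(est.cluster_pvalues_) < 0.05
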
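"""Nonparametric spatio-temporal cluster randomization test.

Band-power time courses (observations x sensors x samples) are contrasted
between two groups with a samplewise t-test; suprathreshold samples (two-
tail p < 0.05) are clustered by time adjacency (consecutive samples at a
sensor) and space adjacency (neighbouring sensors at a sample), keeping
positive and negative t in separate clusters.  Each cluster's mass is the
sum of its t-values.  Significance is assessed against the permutation
distribution of the maximum |sum-of-t| over random relabelings (label
shuffles for independent groups, per-pair sign flips for paired designs),
which controls the family-wise error over all sensors and samples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from ._utils import substream

__all__ = [
    "Cluster", "ClusterResult", "ClusterPermutationTest",
    "samplewise_stat", "form_clusters", "cluster_test",
]


@dataclass
class Cluster:
    """A sign-homogeneous connected set of suprathreshold sensor-time samples."""

    sensors: np.ndarray   # member sensor indices (parallel to samples)
    samples: np.ndarray   # member sample indices
    sum_t: float
    p: float | None = None

    @property
    def size(self) -> int:
        return self.sensors.size

    def members(self) -> set[tuple[int, int]]:
        return set(zip(self.sensors.tolist(), self.samples.tolist()))


@dataclass
class ClusterResult:
    t_map: np.ndarray
    threshold: float
    clusters: list[Cluster]
    null_max: np.ndarray
    alpha_cluster: float
    n_permutations: int
    design: str = "independent"
    exhaustive: bool = False

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p <= self.alpha_cluster]


# ---------------------------------------------------------------------------
# samplewise statistics
# ---------------------------------------------------------------------------

def _t_independent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(0), b.mean(0)
    va = a.var(0, ddof=1)
    vb = b.var(0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def _t_paired(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m, s = d.mean(0), d.std(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where(s > 0, t, 0.0)


def samplewise_stat(group_a: np.ndarray, group_b: np.ndarray,
                    design: str = "independent", threshold_p: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per sensor-and-sample t-map and its two-tail suprathreshold mask.

    Returns ``(t_map, mask, t_critical)``.  Samples with zero variance get
    t = 0 (with a warning) and can never exceed the threshold.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must be observations x sensors x samples "
                         "with matching sensor/sample dimensions")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in the input; crop band-power "
                         "time courses to the valid analysis window first")
    if design == "independent":
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need at least 2 observations per group")
        df = a.shape[0] + b.shape[0] - 2
        t = _t_independent(a, b)
    elif design == "paired":
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired design requires equal, matched groups")
        if a.shape[0] < 2:
            raise ValueError("need at least 2 pairs")
        df = a.shape[0] - 1
        t = _t_paired(a - b)
    else:
        raise ValueError("design must be 'independent' or 'paired'")
    if (t == 0).any() and ((a.var(0) == 0) | (b.var(0) == 0)).any():
        warnings.warn("zero-variance samples encountered; their t set to 0",
                      stacklevel=2)
    tcrit = float(stats.t.ppf(1.0 - threshold_p / 2.0, df))
    return t, np.abs(t) > tcrit, tcrit


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _adjacency_pairs(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    adjacency = np.asarray(adjacency, dtype=bool)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    return iu, ju


def _components(mask: np.ndarray, iu: np.ndarray, ju: np.ndarray
                ) -> tuple[np.ndarray, int, np.ndarray]:
    """Connected component label per masked pixel of one sign.

    Returns (labels over masked pixels, n_components, flat indices of the
    masked pixels in C order).
    """
    n_sens, n_samp = mask.shape
    flat = np.nonzero(mask.ravel())[0]
    k = flat.size
    if k == 0:
        return np.empty(0, dtype=int), 0, flat
    ids = -np.ones(mask.size, dtype=np.int64)
    ids[flat] = np.arange(k)
    rows, cols = [], []
    # time adjacency: consecutive samples at the same sensor
    s, t = np.nonzero(mask[:, :-1] & mask[:, 1:])
    rows.append(ids[s * n_samp + t])
    cols.append(ids[s * n_samp + t + 1])
    # space adjacency: neighbouring sensors at the same sample
    if iu.size:
        both = mask[iu, :] & mask[ju, :]
        p, t2 = np.nonzero(both)
        rows.append(ids[iu[p] * n_samp + t2])
        cols.append(ids[ju[p] * n_samp + t2])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g = csr_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(k, k))
    n_comp, labels = connected_components(g, directed=False)
    return labels, n_comp, flat


def form_clusters(t_map: np.ndarray, mask: np.ndarray, adjacency: np.ndarray,
                  times: np.ndarray | None = None) -> list[Cluster]:
    """Sign-homogeneous connected clusters of suprathreshold samples.

    Ordered by |sum-of-t| descending; ties broken by the lexicographically
    smallest (sensor, sample) member.
    """
    iu, ju = _adjacency_pairs(adjacency)
    n_samp = t_map.shape[1]
    clusters: list[Cluster] = []
    for sign_mask in (mask & (t_map > 0), mask & (t_map < 0)):
        labels, n_comp, flat = _components(sign_mask, iu, ju)
        if n_comp == 0:
            continue
        tvals = t_map.ravel()[flat]
        masses = np.bincount(labels, weights=tvals, minlength=n_comp)
        for c in range(n_comp):
            member = flat[labels == c]
            clusters.append(Cluster(member // n_samp, member % n_samp,
                                    float(masses[c])))
    clusters.sort(key=lambda c: (-abs(c.sum_t),
                                 int(c.sensors.min()), int(c.samples.min())))
    return clusters


def _max_cluster_mass(t_map: np.ndarray, tcrit: float,
                      iu: np.ndarray, ju: np.ndarray) -> float:
    """Maximum |sum-of-t| over the clusters of one (permuted) t-map."""
    best = 0.0
    for sign_mask in (t_map > tcrit, t_map < -tcrit):
        labels, n_comp, flat = _components(sign_mask, iu, ju)
        if n_comp == 0:
            continue
        masses = np.bincount(labels, weights=t_map.ravel()[flat], minlength=n_comp)
        best = max(best, float(np.abs(masses).max()))
    return best


# ---------------------------------------------------------------------------
# the randomization test
# ---------------------------------------------------------------------------

class ClusterPermutationTest(BaseEstimator):
    """Cluster-mass randomization test with max-statistic FWER control.

    Parameters
    ----------
    adjacency : (n_sensors, n_sensors) bool array
        Spatial neighbourhood matrix.
    design : {"independent", "paired"}
        Exchange scheme: full label shuffles, or per-pair sign flips.
    n_permutations : int
        Requested number of random relabelings (>= 100).  When fewer
        distinct relabelings exist, all of them are enumerated instead
        (with a warning).
    threshold_p : float
        Two-tail samplewise p forming the suprathreshold mask.
    alpha : float
        Cluster-level corrected significance threshold (use 0.01 when the
        test is run for several frequency bands).
    random_state : int
        Seed of the permutation stream.

    After ``fit(X, y)`` (X: observations x sensors x samples, y: two group
    labels), the attributes ``t_obs_``, ``clusters_``, ``cluster_pvalues_``,
    ``null_max_`` and ``result_`` are available.
    """

    def __init__(self, adjacency=None, design: str = "independent",
                 n_permutations: int = 1000, threshold_p: float = 0.05,
                 alpha: float = 0.05, random_state: int = 0):
        self.adjacency = adjacency
        self.design = design
        self.n_permutations = n_permutations
        self.threshold_p = threshold_p
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be observations x sensors x samples")
        groups = np.unique(y)
        if groups.size != 2:
            raise ValueError("y must contain exactly two group labels")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        a, b = X[y == groups[0]], X[y == groups[1]]
        self.result_ = _cluster_test_impl(
            a, b, self.adjacency, self.design, self.n_permutations,
            self.threshold_p, self.alpha, self.random_state)
        self.t_obs_ = self.result_.t_map
        self.clusters_ = self.result_.clusters
        self.cluster_pvalues_ = np.array([c.p for c in self.clusters_])
        self.null_max_ = self.result_.null_max
        return self


def _cluster_test_impl(a, b, adjacency, design, n_permutations, threshold_p,
                       alpha, seed) -> ClusterResult:
    t_obs, mask, tcrit = samplewise_stat(a, b, design, threshold_p)
    iu, ju = _adjacency_pairs(adjacency)
    clusters = form_clusters(t_obs, mask, adjacency)

    n_sens, n_samp = t_obs.shape
    na, nb = a.shape[0], b.shape[0]
    rng = substream(seed, "cluster-permutations")
    exhaustive = False

    if design == "independent":
        pooled = np.concatenate([a, b], axis=0)
        flat = pooled.reshape(na + nb, -1)
        flat2 = flat**2
        tot1, tot2 = flat.sum(0), flat2.sum(0)
        n_distinct = comb(na + nb, na) if na + nb <= 60 else None
        if n_distinct is not None and n_distinct <= n_permutations:
            warnings.warn(f"only {n_distinct} distinct relabelings; "
                          "enumerating exhaustively", stacklevel=2)
            exhaustive = True
            assignments = itertools.combinations(range(na + nb), na)
            n_used = n_distinct
        else:
            assignments = (rng.permutation(na + nb)[:na]
                           for _ in range(n_permutations))
            n_used = n_permutations
        null = np.empty(n_used)
        df = na + nb - 2
        for i, idx_a in enumerate(assignments):
            idx_a = np.fromiter(idx_a, dtype=int) if not isinstance(idx_a, np.ndarray) else idx_a
            sa1 = flat[idx_a].sum(0)
            sa2 = flat2[idx_a].sum(0)
            t = _t_from_sums(sa1, sa2, tot1 - sa1, tot2 - sa2, na, nb)
            null[i] = _max_cluster_mass(t.reshape(n_sens, n_samp), tcrit, iu, ju)
    else:  # paired
        d = (a - b).reshape(na, -1)
        d2sum = (d**2).sum(0)
        if na <= 30 and 2**na <= n_permutations:
            warnings.warn(f"only {2**na} distinct sign flips; "
                          "enumerating exhaustively", stacklevel=2)
            exhaustive = True
            signs_iter = itertools.product((1.0, -1.0), repeat=na)
            n_used = 2**na
        else:
            signs_iter = (rng.choice([1.0, -1.0], size=na)
                          for _ in range(n_permutations))
            n_used = n_permutations
        null = np.empty(n_used)
        for i, s in enumerate(signs_iter):
            s = np.asarray(s)
            m = s @ d / na
            var = (d2sum - na * m**2) / (na - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / np.sqrt(var / na)
            t = np.where(var > 0, t, 0.0)
            null[i] = _max_cluster_mass(t.reshape(n_sens, n_samp), tcrit, iu, ju)

    for c in clusters:
        # small relative tolerance so the identity relabeling always counts
        # (the permutation path computes t from running sums, whose result
        # can differ from the direct path in the last float bits)
        thresh = abs(c.sum_t) * (1.0 - 1e-9)
        c.p = float((1 + np.sum(null >= thresh)) / (1 + n_used))
    return ClusterResult(t_obs, tcrit, clusters, null, alpha, n_used,
                         design, exhaustive)


def _t_from_sums(sa1, sa2, sb1, sb2, na, nb):
    ma, mb = sa1 / na, sb1 / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = (sb2 - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.clip(sp2, 0.0, None) * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def cluster_test(group_a, group_b, adjacency, design: str = "independent",
                 n_permutations: int = 1000, seed: int = 0,
                 threshold_p: float = 0.05, alpha: float = 0.05
                 ) -> ClusterResult:
    """Functional wrapper over :class:`ClusterPermutationTest`."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    X = np.concatenate([a, b], axis=0)
    y = np.r_[np.zeros(a.shape[0], int), np.ones(b.shape[0], int)]
    est = ClusterPermutationTest(adjacency=adjacency, design=design,
                                 n_permutations=n_permutations,
                                 threshold_p=threshold_p, alpha=alpha,
                                 random_state=seed)
    est.fit(X, y)
    return est.result_
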
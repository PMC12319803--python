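"""Delta-power statistic and nonparametric cluster-based permutation tests.

Within a participant, the after-effect of stimulation is summarised by
"delta power": a two-sample t statistic contrasting per-trial
post-stimulation power against per-trial (time-averaged) baseline power at
each (unit, frequency-offset, time) element.  At the group level, paired t
values between the tACS and control conditions are thresholded at an a
priori probability (p < 0.05, two-tailed), adjacent suprathreshold elements
are merged into clusters (spatial unit graph, or 4-neighbour grids over
time-frequency / modulation-carrier planes), and each cluster's summed t is
evaluated against the permutation distribution of the maximum summed
cluster statistic obtained by randomly exchanging the two condition labels
within participants (sign flips of the paired differences).

When ``2**n_participants <= n_permutations`` the sign-flip null is
enumerated exhaustively (the identity assignment included), making the
reported p values exact; otherwise ``n_permutations`` random flips are
drawn and the p value uses the standard +1 correction so it is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .data_core import UnitLayout
from .spectral import AlignedTFR


@dataclass
class DeltaPowerMap:
    """Per-participant, per-condition delta-power statistic map."""

    values: np.ndarray  # (unit, offset, time) or any element shape
    participant: str | int = ""
    condition: str = ""
    block: str = ""
    n_post: int = 0
    n_base: int = 0


@dataclass(frozen=True)
class ClusterTestSpec:
    alpha_form: float = 0.05
    tails: str = "two"
    min_cluster_size: int = 2
    n_permutations: int = 1000
    seed: int = 0
    adjacency_domain: str = "space"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_form < 1.0):
            raise ValueError("alpha_form must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tails != "two":
            raise ValueError("only two-tailed cluster forming is supported")


@dataclass
class Cluster:
    members: np.ndarray  # flat element indices
    sum_t: float
    sign: int
    p: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    perm_max: np.ndarray
    spec: ClusterTestSpec
    seed: int
    exhaustive: bool
    shape: tuple[int, ...]

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def delta_power(
    post: np.ndarray,
    baseline: np.ndarray,
    variance: str = "pooled",
    **meta,
) -> DeltaPowerMap:
    """Two-sample t of post vs baseline power, per element.

    ``post``: per-trial power, shape (n_post_trials, ..., n_times).
    ``baseline``: per-trial power, shape (n_base_trials, ..., n_times) or
    (n_base_trials, ...); a trailing time axis is averaged away first, so
    each baseline trial contributes a single value per element.
    ``variance='pooled'`` uses the pooled variance (default);
    ``'welch'`` uses Welch's unequal-variance form.
    """
    post = np.asarray(post, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.ndim == post.ndim:  # average baseline over its time axis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            baseline = np.nanmean(baseline, axis=-1)
    if baseline.ndim != post.ndim - 1:
        raise ValueError("baseline must match post up to the time axis")
    n1, n2 = post.shape[0], baseline.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per segment class")
    m1 = post.mean(axis=0)
    m2 = baseline.mean(axis=0)[..., None]
    v1 = post.var(axis=0, ddof=1)
    v2 = baseline.var(axis=0, ddof=1)[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        if variance == "pooled":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        elif variance == "welch":
            se = np.sqrt(v1 / n1 + v2 / n2)
        else:
            raise ValueError(f"unknown variance form {variance!r}")
        diff = m1 - m2
        t = diff / se
    degenerate = (se == 0) & np.isfinite(diff)
    if np.any(degenerate & (diff != 0)):
        raise ValueError("degenerate variance: zero spread with unequal means")
    t = np.where(degenerate, 0.0, t)
    return DeltaPowerMap(values=t, n_post=n1, n_base=n2, **meta)


def delta_power_from_aligned(
    post: AlignedTFR, baseline: AlignedTFR, variance: str = "pooled", **meta
) -> DeltaPowerMap:
    """Delta power from aligned TFRs, skipping flagged trials."""
    p = post.power[post.good_trials()]
    b = baseline.power[baseline.good_trials()]
    return delta_power(p, b, variance=variance, **meta)


def pool_blocks(
    a: DeltaPowerMap, b: DeltaPowerMap, time_average: bool = False
) -> DeltaPowerMap:
    """Pool the 10 s and 30 s blocks: element-wise average of the two maps.

    ``time_average=True`` additionally averages the pooled map over its
    trailing (time) axis, the form entering the spatial test.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("block maps have mismatching axes")
    vals = 0.5 * (a.values + b.values)
    if time_average:
        vals = np.nanmean(vals, axis=-1)
    return DeltaPowerMap(
        values=vals, participant=a.participant, condition=a.condition,
        block="pooled", n_post=a.n_post + b.n_post,
        n_base=a.n_base + b.n_base,
    )


def grid_adjacency(shape: tuple[int, ...]) -> np.ndarray:
    """4-neighbour lattice adjacency over the flattened multi-index."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    adj = np.zeros((n, n), dtype=bool)
    for axis in range(len(shape)):
        a = np.moveaxis(idx, axis, 0)
        lo, hi = a[:-1].ravel(), a[1:].ravel()
        adj[lo, hi] = True
        adj[hi, lo] = True
    return adj


def spatial_adjacency(layout: UnitLayout) -> np.ndarray:
    return layout.adjacency.copy()


def _group_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t across participants (paired tACS-control differences)."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    s = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where((s == 0) & (m == 0), 0.0, t)


def _find_clusters(
    t: np.ndarray,
    crit: float,
    adj: scipy.sparse.csr_matrix,
    min_size: int,
) -> list[tuple[np.ndarray, float, int]]:
    """Connected suprathreshold clusters of |t| > crit, split by sign."""
    out = []
    finite = np.isfinite(t)
    for sign in (1, -1):
        mask = finite & (sign * t > crit)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = scipy.sparse.csgraph.connected_components(
            sub, directed=False
        )
        for c in range(n_comp):
            members = idx[labels == c]
            if len(members) < min_size:
                continue
            out.append((members, float(t[members].sum()), sign))
    return out


def _perm_signs(n: int, spec: ClusterTestSpec) -> tuple[np.ndarray, bool]:
    if 2**n <= spec.n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        return signs, True
    rng = np.random.default_rng(spec.seed)
    signs = rng.choice([1.0, -1.0], size=(spec.n_permutations, n))
    return signs, False


def cluster_permutation_test(
    tacs: np.ndarray,
    control: np.ndarray,
    spec: ClusterTestSpec,
    adjacency: np.ndarray,
) -> ClusterTestResult:
    """Group-level cluster permutation test of tACS vs control maps.

    ``tacs`` / ``control``: paired per-participant maps, shape
    (n_participants, *element_shape); ``adjacency`` is a symmetric boolean
    matrix over the flattened elements.  Elements with non-finite group t
    (e.g. missing TFR bins) never enter clusters.
    """
    tacs = np.asarray(tacs, dtype=float)
    control = np.asarray(control, dtype=float)
    if tacs.shape != control.shape:
        raise ValueError("condition maps have mismatching shapes")
    n = tacs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    shape = tacs.shape[1:]
    n_elem = int(np.prod(shape))
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_elem, n_elem):
        raise ValueError("adjacency shape must match the element count")
    if not adjacency.any():
        raise ValueError("empty adjacency")
    adj = scipy.sparse.csr_matrix(adjacency)

    d = (tacs - control).reshape(n, n_elem)
    crit = float(scipy.stats.t.ppf(1.0 - spec.alpha_form / 2.0, df=n - 1))
    t_obs = _group_t(d)
    observed = _find_clusters(t_obs, crit, adj, spec.min_cluster_size)

    signs, exhaustive = _perm_signs(n, spec)
    # variance of sign-flipped differences is flip-invariant: vectorise
    ss = np.nansum(d * d, axis=0)
    means = signs @ np.nan_to_num(d) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (ss - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where((var == 0) & (means == 0), 0.0, t_perm)
    nanmask = ~np.isfinite(d).all(axis=0)
    t_perm[:, nanmask] = np.nan

    perm_max = np.zeros(len(signs))
    for i in range(len(signs)):
        cl = _find_clusters(t_perm[i], crit, adj, spec.min_cluster_size)
        if cl:
            perm_max[i] = max(abs(s) for _, s, _ in cl)

    clusters = []
    for members, sum_t, sign in observed:
        count = int(np.sum(perm_max >= abs(sum_t) - 1e-12))
        if exhaustive:
            p = count / len(signs)
        else:
            p = (1 + count) / (len(signs) + 1)
        clusters.append(Cluster(members=members, sum_t=sum_t, sign=sign, p=p))
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(
        clusters=clusters, t_obs=t_obs.reshape(shape), perm_max=perm_max,
        spec=spec, seed=spec.seed, exhaustive=exhaustive, shape=shape,
    )


def region_split_test(
    tacs_maps: np.ndarray,
    control_maps: np.ndarray,
    cluster_units: np.ndarray,
    layout: UnitLayout,
    spec: ClusterTestSpec,
    regions: tuple[str, ...] = ("somatosensory", "frontal"),
) -> dict[str, ClusterTestResult]:
    """Time-frequency cluster tests within each region of a spatial cluster.

    ``*_maps``: per-participant delta-power maps, shape
    (n_participants, n_units, n_offsets, n_times).  For each region the maps
    are averaged over ``cluster_units`` that carry that region label, and a
    cluster test over the offset x time grid is run.
    """
    cluster_units = np.asarray(cluster_units)
    results = {}
    for region in regions:
        units = np.intersect1d(cluster_units, layout.units_in_region(region))
        if len(units) == 0:
            raise ValueError(
                f"cluster has no units in region {region!r}"
            )
        t_maps = tacs_maps[:, units].mean(axis=1)
        c_maps = control_maps[:, units].mean(axis=1)
        adj = grid_adjacency(t_maps.shape[1:])
        results[region] = cluster_permutation_test(t_maps, c_maps, spec, adj)
    return results


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U statistic of the first sample, p).  Fully tied input (all
    pooled values identical) yields the null U and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class BlockContrastResult:
    u_stat: float
    p: float
    t_values: dict[str, np.ndarray] = field(default_factory=dict)


def block_contrast(
    tacs_by_block: dict[str, np.ndarray],
    control_by_block: dict[str, np.ndarray],
    cluster_units: np.ndarray,
) -> BlockContrastResult:
    """Train-duration contrast within the significant spatial cluster.

    Inputs are per-block spatial maps (n_participants, n_units) of delta
    power at ISF (time-averaged).  Per block, a paired group t value is
    computed for every cluster unit; the two sets of cluster-member t
    values are then compared with the rank-sum test.
    """
    cluster_units = np.asarray(cluster_units)
    if len(cluster_units) < 2:
        raise ValueError("cluster must contain at least 2 units")
    blocks = list(tacs_by_block)
    if len(blocks) != 2 or set(blocks) != set(control_by_block):
        raise ValueError("need the same two blocks in both conditions")
    t_values = {}
    for blk in blocks:
        d = tacs_by_block[blk][:, cluster_units] \
            - control_by_block[blk][:, cluster_units]
        t_values[blk] = _group_t(d)
    u, p = rank_sum_test(t_values[blocks[0]], t_values[blocks[1]])
    return BlockContrastResult(u_stat=u, p=p, t_values=t_values)
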
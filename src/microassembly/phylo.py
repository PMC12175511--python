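"""Phylogenetic community structure: patristic distances, MNTD, and the
nearest taxon index (NTI).

NTI is the negated z-score of a community's observed mean nearest taxon
distance against a null distribution obtained by shuffling tip labels across
the taxon pool (equivalently, by drawing random communities of the same size
from the pool).  Positive NTI means the community is more phylogenetically
clustered than expected by chance — the signature of homogeneous selection —
while values near zero indicate phylogenetically random (neutral) assembly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import dendropy
import numpy as np
from numba import njit
from scipy import stats

from .tables import DataError


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path-length matrix of a tree with branch lengths.

    Accumulates, for every internal node, the cross-pairs of its child
    subtrees (d(a, b) = depth_a + depth_b - 2 * depth_lca), which visits each
    tip pair exactly once.  Returns (tip labels, symmetric matrix).
    """
    tips = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in tips]
    index = {id(leaf): i for i, leaf in enumerate(tips)}
    n = len(tips)

    depth = {}
    root = tree.seed_node
    depth[id(root)] = 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise DataError("tree has an edge without branch length")
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)

    tip_depth = np.array([depth[id(t)] for t in tips])
    dist = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = np.array([index[id(node)]], dtype=np.int64)
            continue
        children = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d_node = depth[id(node)]
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                a, b = children[i], children[j]
                block = tip_depth[a][:, None] + tip_depth[b][None, :] - 2.0 * d_node
                dist[np.ix_(a, b)] = block
                dist[np.ix_(b, a)] = block.T
        tipsets[id(node)] = np.concatenate(children)
    return labels, dist


@njit(cache=True)
def _mntd_unweighted(dist: np.ndarray, idx: np.ndarray) -> float:
    k = idx.size
    total = 0.0
    for a in range(k):
        best = np.inf
        ia = idx[a]
        for b in range(k):
            if a == b:
                continue
            d = dist[ia, idx[b]]
            if d < best:
                best = d
        total += best
    return total / k


@njit(cache=True)
def _mntd_weighted(dist: np.ndarray, idx: np.ndarray, w: np.ndarray) -> float:
    k = idx.size
    total = 0.0
    wsum = 0.0
    for a in range(k):
        best = np.inf
        ia = idx[a]
        for b in range(k):
            if a == b:
                continue
            d = dist[ia, idx[b]]
            if d < best:
                best = d
        total += w[a] * best
        wsum += w[a]
    return total / wsum


@njit(cache=True)
def _mntd_many(dist: np.ndarray, idx_matrix: np.ndarray) -> np.ndarray:
    n = idx_matrix.shape[0]
    out = np.empty(n)
    for r in range(n):
        out[r] = _mntd_unweighted(dist, idx_matrix[r])
    return out


def neighbor_cache(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-tip neighbors sorted by distance, for fast nearest-member lookups.

    Returns ``(order, dsorted)`` where ``order[i]`` lists all tips by
    increasing distance from tip i and ``dsorted[i]`` the matching distances.
    Precompute once per taxon pool and pass to :func:`nti` when scoring many
    communities over the same pool.
    """
    order = np.argsort(dist, axis=1).astype(np.int64)
    dsorted = np.take_along_axis(dist, order, axis=1)
    return order, dsorted


@njit(cache=True)
def _mntd_many_cached(order, dsorted, idx_matrix, pool):
    """MNTD of many communities via sorted-neighbor scans.

    For each member, walk its distance-sorted neighbor list until the first
    other community member; expected scan length is pool/k, so a whole
    community costs ~O(pool) instead of O(k^2).
    """
    n = idx_matrix.shape[0]
    out = np.empty(n)
    mask = np.zeros(pool, dtype=np.bool_)
    for r in range(n):
        idx = idx_matrix[r]
        k = idx.size
        for a in range(k):
            mask[idx[a]] = True
        total = 0.0
        for a in range(k):
            i = idx[a]
            for pos in range(pool):
                j = order[i, pos]
                if j != i and mask[j]:
                    total += dsorted[i, pos]
                    break
        out[r] = total / k
        for a in range(k):
            mask[idx[a]] = False
    return out


def mntd(
    community_taxa: Sequence[str],
    labels: Sequence[str],
    dist: np.ndarray,
    abundance_weights: Sequence[float] | None = None,
) -> float:
    """Mean nearest taxon distance of a community.

    For each community member, the distance to its closest *other* member;
    averaged either uniformly or by abundance weights.
    """
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [t for t in community_taxa if t not in pos]
    if missing:
        raise DataError(f"taxa absent from distance matrix: {missing[:5]}")
    if len(community_taxa) < 2:
        raise DataError("MNTD needs at least 2 taxa")
    idx = np.array([pos[t] for t in community_taxa], dtype=np.int64)
    if abundance_weights is None:
        return float(_mntd_unweighted(dist, idx))
    w = np.asarray(abundance_weights, dtype=float)
    if w.shape[0] != idx.size or np.any(w < 0) or w.sum() == 0:
        raise DataError("weights must be non-negative, matching the community")
    return float(_mntd_weighted(dist, idx, w))


# ---------------------------------------------------------------------------
# NTI
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NtiResult:
    community_id: str
    mntd_obs: float
    null_mean: float
    null_sd: float
    nti: float          # NaN when undefined
    n_null: int
    weighted: bool
    undefined: bool = False


def nti(
    community_taxa: Sequence[str],
    labels: Sequence[str],
    dist: np.ndarray,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    community_id: str = "",
    abundance_weights: Sequence[float] | None = None,
    cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> NtiResult:
    """Nearest taxon index against the taxa-label shuffle null.

    The null shuffles tip labels among the pool (the rows of `dist`), which
    is equivalent to drawing random communities of the observed size; NTI is
    ``-(mntd_obs - null_mean) / null_sd``.  When the community equals the
    whole pool, MNTD is shuffle-invariant and the index is flagged undefined.
    """
    if n_null < 99:
        raise DataError("n_null must be at least 99")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = mntd(community_taxa, labels, dist, abundance_weights)
    pool = len(labels)
    k = len(set(community_taxa))

    if k >= pool:
        return NtiResult(community_id, obs, obs, 0.0, float("nan"),
                         n_null, abundance_weights is not None, undefined=True)

    idx_matrix = np.empty((n_null, k), dtype=np.int64)
    for r in range(n_null):
        idx_matrix[r] = rng.choice(pool, size=k, replace=False)
    if cache is None:
        null = _mntd_many(dist, idx_matrix)
    else:
        null = _mntd_many_cached(cache[0], cache[1], idx_matrix, pool)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return NtiResult(community_id, obs, mu, 0.0, float("nan"),
                         n_null, abundance_weights is not None, undefined=True)
    z = -(obs - mu) / sd
    return NtiResult(community_id, obs, mu, sd, float(z),
                     n_null, abundance_weights is not None)


# ---------------------------------------------------------------------------
# per-plot tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlotTest:
    location: str
    plot: int
    nti_values: list[float]
    t_statistic: float
    p_two_sided: float
    significant: bool
    zero_variance: bool = False


def plot_level_test(
    nti_values: Sequence[float], location: str = "", plot: int = 0, alpha: float = 0.05
) -> PlotTest:
    """Two-sided one-sample t-test of a plot's NTI values against zero."""
    vals = [v for v in nti_values if v == v]  # drop NaN (undefined NTI)
    if len(vals) < 2:
        raise DataError("need at least 2 NTI values per plot")
    arr = np.asarray(vals, dtype=float)
    if arr.std(ddof=1) == 0:
        return PlotTest(location, plot, vals, float("nan"), float("nan"),
                        False, zero_variance=True)
    t, p = stats.ttest_1samp(arr, 0.0)
    return PlotTest(location, plot, vals, float(t), float(p), bool(p < alpha))
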
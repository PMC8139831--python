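"""Skeleton-derived developmental proxies.

Birth order in the ventral nerve cord is laid down radially: early-born
neurons sit deep in the cortex next to the neuropil and late-born neurons
superficially, so the geodesic path length from the soma to the point where
the neurite enters the neuropil ("cortex neurite length") is a proxy for
birth order.  This module computes that proxy, bins it into four temporal
groups calibrated on reference populations of identified early (Hb+) and
late (Cas+) neurons, and clusters neurons into hemilineages from skeleton
morphology via a tangent-weighted Gaussian point-cloud kernel after
Strahler pruning of terminal twigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .core import NeuropilVolume, Skeleton

#: Dendrogram height (on 1 - mean normalized score distances) at which
#: per-lineage morphology dendrograms are cut into hemilineages.  Calibrated
#: on the synthetic two-hemilineage fixture, where dorsal/ventral arbors are
#: separated by far more than the arbor spread and any cutoff in a wide band
#: recovers exactly two clusters.
DEFAULT_CLUSTER_CUTOFF = 0.9


# ---------------------------------------------------------------------------
# Strahler order and pruning
# ---------------------------------------------------------------------------


def strahler_order(skeleton: Skeleton) -> dict[int, int]:
    """Strahler branch order per node (leaves have order 1).

    A parent segment has order ``m + 1`` where ``m`` is the highest child
    order attained by two or more children, otherwise the maximum child
    order.
    """
    n = skeleton.n_nodes
    order = np.zeros(n, dtype=int)
    # children counts for a post-order traversal without recursion
    pending = np.array([len(skeleton.children_of(k)) for k in range(n)])
    stack = [k for k in range(n) if pending[k] == 0]
    order[pending == 0] = 1
    pidx = skeleton.parent_index
    remaining = pending.copy()
    while stack:
        k = stack.pop()
        p = pidx[k]
        if p < 0:
            continue
        remaining[p] -= 1
        if remaining[p] == 0:
            child_orders = [order[c] for c in skeleton.children_of(p)]
            m = max(child_orders)
            order[p] = m + 1 if child_orders.count(m) >= 2 else m
            stack.append(p)
    return {int(skeleton.node_ids[k]): int(order[k]) for k in range(n)}


def prune_by_strahler(skeleton: Skeleton, keep_min_order: int) -> Skeleton:
    """Remove distal twigs below a Strahler order.

    Returns the subtree of nodes with order >= ``keep_min_order``; the root
    is always retained.  Orders are non-increasing from root to leaf, so the
    kept set is automatically root-connected.
    """
    if keep_min_order < 1:
        raise ValueError("keep_min_order must be >= 1")
    orders = strahler_order(skeleton)
    keep = np.array([orders[int(i)] >= keep_min_order for i in skeleton.node_ids])
    keep[skeleton.root_index] = True
    if keep.sum() == 1 and skeleton.n_nodes > 1:
        warnings.warn(
            f"keep_min_order={keep_min_order} exceeds the maximum Strahler order; "
            "returning a root-only skeleton",
            stacklevel=2,
        )
    return skeleton.subset(keep)


# ---------------------------------------------------------------------------
# Cortex neurite length and temporal binning
# ---------------------------------------------------------------------------


def neuropil_entry(skeleton: Skeleton, volume: NeuropilVolume) -> int | None:
    """Node id of the neuropil entry point, or None if the arbor never enters.

    The entry point is the in-volume node with minimal geodesic distance
    from the root (ties broken by node order).
    """
    inside = volume.contains(skeleton.coords)
    if not inside.any():
        return None
    dist = skeleton.distances_to_root()
    candidates = np.flatnonzero(inside)
    best = candidates[np.argmin(dist[candidates])]
    return int(skeleton.node_ids[best])


def cortex_neurite_length(skeleton: Skeleton, volume: NeuropilVolume) -> float | None:
    """Geodesic distance (nm) from the soma to the neuropil entry point."""
    entry = neuropil_entry(skeleton, volume)
    if entry is None:
        return None
    return float(skeleton.distances_to_root()[skeleton.index_of(entry)])


def bilateral_mean_length(left: float | None, right: float | None) -> float | None:
    """Mean of the left/right cortex lengths of a homologous neuron pair.

    If one side is undefined the other is propagated with a warning; if both
    are undefined the result is None.
    """
    if left is None and right is None:
        return None
    if left is None or right is None:
        warnings.warn("one side of a homolog pair has no cortex length; using the other side",
                      stacklevel=2)
        return float(left if right is None else right)
    return 0.5 * (float(left) + float(right))


@dataclass(frozen=True)
class TemporalBinning:
    """Cortex-length cut points separating the four temporal groups.

    ``t1 = mean(Hb) + sd(Hb)`` bounds the early-born group; ``t2 =
    mean(Cas) - sd(Cas)`` opens the Cas window and ``t3 = mean(Cas)`` splits
    the final two groups.  Standard deviations are sample (n-1) estimates.
    """

    t1: float
    t2: float
    t3: float
    n_hb: int
    n_cas: int

    def __post_init__(self) -> None:
        if not (self.t1 <= self.t2 <= self.t3):
            raise ValueError(
                "reference populations overlap too much to define four ordered bins: "
                f"t1={self.t1:.1f}, t2={self.t2:.1f}, t3={self.t3:.1f}"
            )


def fit_temporal_bins(hb_lengths, cas_lengths) -> TemporalBinning:
    """Fit temporal cut points from reference Hb+ and Cas+ cortex lengths."""
    hb = np.asarray(hb_lengths, dtype=float)
    cas = np.asarray(cas_lengths, dtype=float)
    if hb.size < 2 or cas.size < 2:
        raise ValueError("need at least two reference lengths per population")
    return TemporalBinning(
        t1=float(hb.mean() + hb.std(ddof=1)),
        t2=float(cas.mean() - cas.std(ddof=1)),
        t3=float(cas.mean()),
        n_hb=int(hb.size),
        n_cas=int(cas.size),
    )


def assign_temporal_group(length, bins: TemporalBinning):
    """Temporal group (1-4) for a cortex neurite length.

    Group 1: ``L < t1``; group 2: ``t1 <= L <= t2``; group 3:
    ``t2 < L <= t3``; group 4: ``L > t3``.  Accepts scalars or arrays.
    """
    arr = np.asarray(length, dtype=float)
    group = np.select(
        [arr < bins.t1, arr <= bins.t2, arr <= bins.t3], [1, 2, 3], default=4
    )
    if np.isscalar(length) or arr.ndim == 0:
        return int(group)
    return group


# ---------------------------------------------------------------------------
# Dotprops and morphological similarity
# ---------------------------------------------------------------------------


@dataclass
class DotProps:
    """Point-cloud representation of a skeleton with local tangents."""

    points: np.ndarray
    tangents: np.ndarray
    spacing: float
    k_neighbors: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if self.points.shape != self.tangents.shape:
            raise ValueError("points and tangents must have matching shapes")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")

    def __len__(self) -> int:
        return len(self.points)


def _linear_segments(skeleton: Skeleton) -> list[np.ndarray]:
    """Decompose the tree into maximal unbranched polylines (proximal first)."""
    n = skeleton.n_nodes
    n_children = np.array([len(skeleton.children_of(k)) for k in range(n)])
    pidx = skeleton.parent_index
    is_endpoint = (n_children != 1) | (pidx < 0)
    segments = []
    for k in range(n):
        if not (n_children[k] == 0 or n_children[k] >= 2):
            continue
        # walk rootward from each leaf/branch node to the previous endpoint
        path = [k]
        u = pidx[k]
        while u >= 0:
            path.append(u)
            if is_endpoint[u]:
                break
            u = pidx[u]
        if len(path) >= 2:
            segments.append(skeleton.coords[path[::-1]])
    return segments


def to_dotprops(skeleton: Skeleton, spacing: float = 1000.0, k: int = 5) -> DotProps:
    """Resample a skeleton at uniform arc length and attach local tangents.

    Each unbranched segment is resampled every ``spacing`` nm (both segment
    endpoints included); the tangent at a point is the dominant principal
    direction of its ``k`` nearest resampled points.  Tangent sign is
    canonicalized (first non-zero component positive) — downstream scores
    use ``|u . v|`` and are sign-blind.
    """
    if skeleton.n_nodes < 2:
        raise ValueError("need at least 2 nodes to build dotprops")
    pts = []
    for poly in _linear_segments(skeleton):
        seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        if total == 0:
            pts.append(poly[:1])
            continue
        targets = np.arange(0.0, total, spacing)
        if total - targets[-1] > 1e-9:
            targets = np.append(targets, total)
        sampled = np.column_stack([np.interp(targets, cum, poly[:, d]) for d in range(3)])
        pts.append(sampled)
    points = np.vstack(pts)
    n = len(points)
    kk = min(max(2, k), n)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=kk)
    idx = np.atleast_2d(idx)
    tangents = np.empty_like(points)
    for i in range(n):
        nbrs = points[idx[i]]
        centered = nbrs - nbrs.mean(axis=0)
        # dominant principal direction of the local neighborhood
        _, vecs = np.linalg.eigh(centered.T @ centered)
        t = vecs[:, -1]
        nz = np.flatnonzero(np.abs(t) > 1e-12)
        if nz.size and t[nz[0]] < 0:
            t = -t
        tangents[i] = t
    return DotProps(points=points, tangents=tangents, spacing=float(spacing), k_neighbors=kk)


def morph_similarity(query: DotProps, target: DotProps, sigma_n: float = 2000.0) -> float:
    """Normalized morphological similarity of two dotprops clouds.

    For each query point, the nearest target point contributes
    ``exp(-d^2 / (2 sigma_n^2)) * |u . v|`` (distance-weighted tangent
    alignment); the raw sum is normalized by the query's self-score, so a
    neuron scored against itself gives exactly 1.  The score is invariant
    under rigid motions applied to both clouds.
    """
    if len(query) == 0 or len(target) == 0:
        raise ValueError("dotprops must be non-empty")
    tree = cKDTree(target.points)
    d, idx = tree.query(query.points)
    align = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    raw = float(np.sum(np.exp(-(d**2) / (2.0 * sigma_n**2)) * align))
    return raw / len(query)  # self raw score = n (d = 0, |u.u| = 1)


def cluster_hemilineages(
    score_matrix: np.ndarray, height_cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> np.ndarray:
    """Cut an average-linkage dendrogram of morphology scores into clusters.

    ``score_matrix`` holds pairwise normalized similarity scores (possibly
    asymmetric); the distance used is ``1 - (S + S.T) / 2``.  Returns
    integer cluster labels (1-based) per neuron.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("score_matrix must be square")
    n = S.shape[0]
    if n == 1:
        return np.array([1])
    D = 1.0 - 0.5 * (S + S.T)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=height_cutoff, criterion="distance")
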
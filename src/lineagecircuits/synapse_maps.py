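"""Synapse-position statistics.

The central quantity is a kernel score comparing the 3D positions of two
neurons' synapse sets.  For each synapse *s* of neuron *i*, let *k* be the
nearest synapse of neuron *j*; the pairwise contribution is

    f(is, jk) = exp(-d_sk^2 / (2 sigma^2)) * exp(-|n_is - n_jk| / (n_is + n_jk))

where ``d_sk`` is the Euclidean distance between *s* and *k*, and ``n_is``
(``n_jk``) is the fraction of neuron *i*'s (*j*'s) synapses within a radius
``omega`` of *s* (*k*).  The directed score is the mean of *f* over the
synapses of *i*: it is high when the two clouds lie close together *and*
have matching local densities.  Defaults are sigma = omega = 2000 nm.

Applied between the presynapses of one neuron and the postsynapses of
another, the same kernel becomes a pre/post *overlap* score — the proximity
proxy for potential connectivity (Peter's rule) used by the null models.

The module also provides Gaussian KDE density maps of synapse clouds over
the transverse (mediolateral x dorsoventral) plane with mass-referenced
outer contours, optionally weighting each presynaptic site by its number of
polyadic targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynapseSimilarityParams:
    """Kernel parameters: bandwidth ``sigma`` and density radius ``omega`` (nm)."""

    sigma: float = 2000.0
    omega: float = 2000.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.omega <= 0:
            raise ValueError("sigma and omega must be positive")


DEFAULT_PARAMS = SynapseSimilarityParams()


def _neighbor_fraction(points: np.ndarray, tree: cKDTree, omega: float) -> np.ndarray:
    """Fraction of the cloud within omega of each point (each point counts itself)."""
    counts = tree.query_ball_point(points, r=omega, return_length=True)
    return np.asarray(counts, dtype=float) / len(points)


def synapse_similarity(
    syn_a: np.ndarray,
    syn_b: np.ndarray,
    params: SynapseSimilarityParams = DEFAULT_PARAMS,
    *,
    symmetric: bool = False,
) -> float:
    """Kernel similarity between two synapse point sets.

    Returns the directed score (mean over the synapses of ``syn_a``); with
    ``symmetric=True`` the mean of the two directed scores.  Identical
    clouds score exactly 1.  Nearest-neighbour ties resolve to the lowest
    index (measure-zero for continuous coordinates).
    """
    a = np.atleast_2d(np.asarray(syn_a, dtype=float))
    b = np.atleast_2d(np.asarray(syn_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("synapse sets must be non-empty")
    score = _directed_similarity(a, b, params)
    if symmetric:
        score = 0.5 * (score + _directed_similarity(b, a, params))
    return score


def _directed_similarity(a: np.ndarray, b: np.ndarray, params: SynapseSimilarityParams) -> float:
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    d, idx = tree_b.query(a)
    n_is = _neighbor_fraction(a, tree_a, params.omega)
    n_b = _neighbor_fraction(b, tree_b, params.omega)
    n_jk = n_b[idx]
    f = np.exp(-(d**2) / (2.0 * params.sigma**2)) * np.exp(
        -np.abs(n_is - n_jk) / (n_is + n_jk)
    )
    return float(f.mean())


def overlap_score(
    pre_a: np.ndarray, post_b: np.ndarray, params: SynapseSimilarityParams = DEFAULT_PARAMS
) -> float:
    """Pre/post overlap: the directed kernel from presynapses of one neuron
    to postsynapses of another.

    By convention an empty cloud on either side gives 0 (logged): a neuron
    with no presynapses cannot overlap anything.
    """
    a = np.asarray(pre_a, dtype=float)
    b = np.asarray(post_b, dtype=float)
    if a.size == 0 or b.size == 0:
        logger.debug("overlap_score: empty synapse set, returning 0 by convention")
        return 0.0
    return synapse_similarity(a, b, params)


def bilateral_average(score_left: float | None, score_right: float | None) -> float | None:
    """Mean of a left-side and a right-side score for one homolog pair.

    A single-sided value is propagated with a warning; two missing sides
    give None.
    """
    if score_left is None and score_right is None:
        return None
    if score_left is None or score_right is None:
        warnings.warn("bilateral_average: one side missing, propagating the other",
                      stacklevel=2)
        return float(score_left if score_right is None else score_right)
    return 0.5 * (float(score_left) + float(score_right))


def similarity_matrix(
    synapses: dict[str, dict[str, np.ndarray]],
    annotations: pd.DataFrame,
    mode: str = "pre_pre",
    params: SynapseSimilarityParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Bilaterally averaged directed similarity over homologous neuron pairs.

    Parameters
    ----------
    synapses
        ``neuron_id -> {"pre": (n,3) array, "post": (m,3) array}``.
    annotations
        Neuron-indexed annotation table with ``hemisegment`` and
        ``homolog_id`` columns.
    mode
        ``pre_pre``, ``post_post`` or ``pre_post`` (the overlap variant).

    Returns
    -------
    DataFrame indexed by the left-hemisegment representative of each
    homolog pair; entry (i, j) is the mean of the left-side and right-side
    directed scores.  Neurons lacking synapses of the needed polarity are
    excluded (logged).  The mode and kernel parameters are stored in
    ``DataFrame.attrs``.
    """
    if mode not in ("pre_pre", "post_post", "pre_post"):
        raise ValueError(f"unknown mode {mode!r}")
    pol_a, pol_b = mode.split("_")

    paired = annotations[annotations["homolog_id"].notna()]
    left = paired[paired["hemisegment"] == "left"]
    homolog_of = {}
    for hid, grp in paired.groupby("homolog_id"):
        sides = grp.set_index("hemisegment")["neuron_id"]
        if {"left", "right"} <= set(sides.index):
            homolog_of[sides["left"]] = sides["right"]

    def usable(nid: str, pol: str) -> bool:
        s = synapses.get(nid)
        return s is not None and np.asarray(s.get(pol, ())).size > 0

    ids = [
        nid
        for nid in left["neuron_id"]
        if nid in homolog_of
        and usable(nid, pol_a)
        and usable(nid, pol_b)
        and usable(homolog_of[nid], pol_a)
        and usable(homolog_of[nid], pol_b)
    ]
    excluded = set(left["neuron_id"]) - set(ids)
    if excluded:
        logger.info("similarity_matrix: excluded %d neurons lacking %s synapses",
                    len(excluded), mode)

    n = len(ids)
    out = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            s_l = synapse_similarity(synapses[a][pol_a], synapses[b][pol_b], params)
            s_r = synapse_similarity(
                synapses[homolog_of[a]][pol_a], synapses[homolog_of[b]][pol_b], params
            )
            out[i, j] = bilateral_average(s_l, s_r)
    df = pd.DataFrame(out, index=ids, columns=ids)
    df.attrs.update({"mode": mode, "sigma": params.sigma, "omega": params.omega})
    return df


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    """A 2D KDE of synapse positions over the transverse plane.

    ``grid`` integrates to 1 over the map extent; ``contour_level`` is the
    density value whose superlevel set encloses ``contour_fraction`` of the
    total mass (mass-referenced contour, not peak-referenced).
    """

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bandwidth: float | str
    contour_fraction: float
    contour_level: float
    weights_policy: str
    marginal_x: np.ndarray = field(default=None, repr=False)
    marginal_y: np.ndarray = field(default=None, repr=False)

    def enclosed_mass(self, level: float | None = None) -> float:
        """Probability mass inside the superlevel set of ``level``."""
        lvl = self.contour_level if level is None else level
        cell = (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        return float(self.grid[self.grid >= lvl].sum() * cell)


def density_map(
    synapses: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth: float | str = "scott",
    contour_fraction: float = 0.6,
    weights_policy: str = "uniform",
    grid_size: int = 128,
    pad: float = 4000.0,
    ap_window: tuple[float, float] | None = None,
) -> DensityMap:
    """Gaussian KDE of synapse positions projected to (mediolateral, dorsoventral).

    Parameters
    ----------
    synapses
        (n, 3) synapse positions in nm; only (x, y) enter the 2D map.
    weights
        Optional per-synapse weights.  Under ``weights_policy='polyadic'``
        callers pass the partner count of each presynaptic site, so a
        polyadic synapse counts as many times as it has targets.
    contour_fraction
        Mass enclosed by the outermost contour (0.6 for hemilineage maps,
        0.8 for whole-lineage maps).
    ap_window
        Optional (z_min, z_max) anteroposterior window; synapses outside it
        are excluded before estimation (positional information degrades
        outside a consistent segment range).
    """
    pts = np.atleast_2d(np.asarray(synapses, dtype=float))
    if not 0 < contour_fraction <= 1:
        raise ValueError("contour_fraction must be in (0, 1]")
    w = None if weights is None else np.asarray(weights, dtype=float)
    if ap_window is not None:
        keep = (pts[:, 2] >= ap_window[0]) & (pts[:, 2] <= ap_window[1])
        pts = pts[keep]
        w = None if w is None else w[keep]
    if len(pts) < 2:
        raise ValueError("need at least 2 synapses for a density map")
    xy = pts[:, :2]

    x_edges = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_size)
    y_edges = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_size)
    xx, yy = np.meshgrid(x_edges, y_edges, indexing="ij")

    spread = xy.std(axis=0)
    if np.all(spread < 1e-9):
        warnings.warn("all synapses identical; returning a point-mass map", stacklevel=2)
        grid = np.zeros((grid_size, grid_size))
        i = np.argmin(np.abs(x_edges - xy[0, 0]))
        j = np.argmin(np.abs(y_edges - xy[0, 1]))
        cell = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
        grid[i, j] = 1.0 / cell
        return DensityMap(grid, x_edges, y_edges, bandwidth, contour_fraction,
                          grid[i, j], weights_policy)

    kde = gaussian_kde(xy.T, bw_method=None if bandwidth == "scott" else bandwidth, weights=w)
    grid = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    grid = grid / (grid.sum() * cell)  # renormalize over the finite extent

    # smallest superlevel set holding >= contour_fraction of the mass
    flat = np.sort(grid.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    k = int(np.searchsorted(cum, contour_fraction))
    level = float(flat[min(k, flat.size - 1)])

    kde_x = gaussian_kde(xy[:, 0], bw_method=None if bandwidth == "scott" else bandwidth,
                         weights=w)
    kde_y = gaussian_kde(xy[:, 1], bw_method=None if bandwidth == "scott" else bandwidth,
                         weights=w)
    return DensityMap(
        grid=grid,
        x_edges=x_edges,
        y_edges=y_edges,
        bandwidth=bandwidth,
        contour_fraction=contour_fraction,
        contour_level=level,
        weights_policy=weights_policy,
        marginal_x=kde_x(x_edges),
        marginal_y=kde_y(y_edges),
    )


def plot_density_map(dmap: DensityMap, path=None, ax=None, cmap: str = "magma"):
    """Render a density map with its outer contour (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    extent = (dmap.x_edges[0], dmap.x_edges[-1], dmap.y_edges[0], dmap.y_edges[-1])
    ax.imshow(dmap.grid.T, origin="lower", extent=extent, aspect="equal", cmap=cmap)
    ax.contour(dmap.x_edges, dmap.y_edges, dmap.grid.T, levels=[dmap.contour_level],
               colors="w", linewidths=1.0)
    ax.set_xlabel("mediolateral (nm)")
    ax.set_ylabel("dorsoventral (nm)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a density map as a gridded text file with a metadata header."""
    header = (
        f"density map; contour_fraction={dmap.contour_fraction}; "
        f"contour_level={dmap.contour_level!r}; weights={dmap.weights_policy}; "
        f"x_edges {dmap.x_edges[0]}..{dmap.x_edges[-1]}; "
        f"y_edges {dmap.y_edges[0]}..{dmap.y_edges[-1]}"
    )
    np.savetxt(path, dmap.grid, header=header)


# ---------------------------------------------------------------------------
# Bulk helpers
# ---------------------------------------------------------------------------


def synapses_from_connectors(connectors) -> dict[str, dict[str, np.ndarray]]:
    """Per-neuron realized synapse clouds from a connector list.

    A neuron's presynapses are the pre-locations of its connectors; its
    postsynapses are the partner sites where it appears as a target (one
    site per (connector, partner) contact, so polyadic synapses count once
    per target).
    """
    pre: dict[str, list] = {}
    post: dict[str, list] = {}
    for c in connectors:
        pre.setdefault(str(c.pre_neuron), []).append(np.asarray(c.pre_location, dtype=float))
        for nid, loc in c.post_partners:
            post.setdefault(str(nid), []).append(np.asarray(loc, dtype=float))
    ids = sorted(set(pre) | set(post))
    return {
        nid: {
            "pre": np.array(pre.get(nid, np.empty((0, 3)))).reshape(-1, 3),
            "post": np.array(post.get(nid, np.empty((0, 3)))).reshape(-1, 3),
        }
        for nid in ids
    }


def overlap_matrix(
    pre_clouds: dict[str, np.ndarray],
    post_clouds: dict[str, np.ndarray],
    params: SynapseSimilarityParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """All-pairs pre/post overlap scores (rows: presynaptic neuron).

    Entry (i, j) equals ``overlap_score(pre_clouds[i], post_clouds[j])``;
    empty clouds give 0 rows/columns by the overlap convention.  KD-trees
    and neighbour fractions are reused across pairs, so this scales to
    hundreds of neurons.
    """
    pre_ids = list(pre_clouds)
    post_ids = list(post_clouds)
    pre_prepared = {}
    for i in pre_ids:
        a = np.asarray(pre_clouds[i], dtype=float).reshape(-1, 3)
        if len(a):
            tree = cKDTree(a)
            pre_prepared[i] = (a, _neighbor_fraction(a, tree, params.omega))
    post_prepared = {}
    for j in post_ids:
        b = np.asarray(post_clouds[j], dtype=float).reshape(-1, 3)
        if len(b):
            tree = cKDTree(b)
            post_prepared[j] = (tree, _neighbor_fraction(b, tree, params.omega))
    out = np.zeros((len(pre_ids), len(post_ids)))
    for xi, i in enumerate(pre_ids):
        if i not in pre_prepared:
            continue
        a, n_is = pre_prepared[i]
        for xj, j in enumerate(post_ids):
            if j not in post_prepared:
                continue
            tree_b, n_b = post_prepared[j]
            d, idx = tree_b.query(a)
            f = np.exp(-(d**2) / (2.0 * params.sigma**2)) * np.exp(
                -np.abs(n_is - n_b[idx]) / (n_is + n_b[idx])
            )
            out[xi, xj] = f.mean()
    df = pd.DataFrame(out, index=pre_ids, columns=post_ids)
    df.attrs.update({"mode": "pre_post", "sigma": params.sigma, "omega": params.omega})
    return df
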
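import numpy as np
import pytest
from hypothesis import given, strategies as st

import lineagecircuits as lc

from conftest import random_tree_skeleton


def chain_skeleton(points, neuron_id="chain"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return lc.Skeleton(
        neuron_id=neuron_id,
        node_ids=np.arange(1, n + 1),
        parent_ids=np.concatenate([[-1], np.arange(1, n)]),
        coords=points,
        radii=np.full(n, 100.0),
    )


def tree_from_edges(coords, parents):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    node_ids = np.arange(1, n + 1)
    parent_ids = np.array([-1 if p is None else p + 1 for p in parents])
    return lc.Skeleton("t", node_ids, parent_ids, coords, np.full(n, 100.0))


# ---------------------------------------------------------------------------
# Strahler order and pruning
# ---------------------------------------------------------------------------


def test_strahler_unbranched_path_all_order_one():
    sk = chain_skeleton([[0, 0, 1000 * i] for i in range(10)])
    assert set(lc.strahler_order(sk).values()) == {1}


def test_strahler_fork_and_twig():
    # 0 -> 1 -> {2, 3}: the stem below the fork has order 2
    sk = tree_from_edges(
        [[0, 0, 0], [0, 0, 1], [1, 0, 2], [-1, 0, 2]], [None, 0, 1, 1]
    )
    orders = lc.strahler_order(sk)
    assert orders[3] == orders[4] == 1
    assert orders[1] == orders[2] == 2

    # an order-2 branch joined by an order-1 twig keeps order 2 downstream
    sk2 = tree_from_edges(
        [[0, 0, 0], [0, 0, 1], [1, 0, 2], [-1, 0, 2], [0, 1, 1], [0, 2, 1]],
        [None, 0, 1, 1, 0, 4],
    )
    orders2 = lc.strahler_order(sk2)
    assert orders2[2] == 2          # fork stem
    assert orders2[5] == orders2[6] == 1  # twig
    assert orders2[1] == 2          # root: max(2, 1) = 2, not 3


def test_prune_identity_and_y_shape():
    sk = tree_from_edges(
        [[0, 0, 0], [0, 0, 1], [1, 0, 2], [-1, 0, 2]], [None, 0, 1, 1]
    )
    same = lc.prune_by_strahler(sk, 1)
    assert same.n_nodes == sk.n_nodes
    pruned = lc.prune_by_strahler(sk, 2)
    assert set(pruned.node_ids) == {1, 2}  # both leaf twigs removed, stem kept


def test_prune_excessive_order_returns_root_only():
    sk = chain_skeleton([[0, 0, 0], [0, 0, 1000]])
    with pytest.warns(UserWarning, match="exceeds"):
        pruned = lc.prune_by_strahler(sk, 99)
    assert pruned.n_nodes == 1
    assert pruned.root == sk.root


# ---------------------------------------------------------------------------
# Neuropil entry and cortex neurite length
# ---------------------------------------------------------------------------

VOLUME = lc.NeuropilVolume(
    "axis_aligned_box", {"min": [2500, -1e6, -1e6], "max": [1e7, 1e6, 1e6]}
)


def test_entry_soma_inside_returns_root():
    sk = chain_skeleton([[5000, 0, 0], [6000, 0, 0]])
    assert lc.neuropil_entry(sk, VOLUME) == sk.root
    assert lc.cortex_neurite_length(sk, VOLUME) == 0.0


def test_entry_first_in_volume_node_along_chain():
    sk = chain_skeleton([[1000 * i, 0, 0] for i in range(6)])  # x = 0..5000
    assert lc.neuropil_entry(sk, VOLUME) == 4  # node at x = 3000
    assert lc.cortex_neurite_length(sk, VOLUME) == pytest.approx(3000.0)


def test_entry_prefers_geodesically_closer_branch():
    # two branches enter the volume at geodesic 4000 and 6000 nm
    sk = tree_from_edges(
        [[0, 0, 0], [2000, 0, 0], [2000, 2000, 0], [2600, 2000, 0],
         [2000, -4000, 0], [3000, -4000, 0]],
        [None, 0, 1, 2, 1, 4],
    )
    entry = lc.neuropil_entry(sk, VOLUME)
    dist = sk.distances_to_root()
    inside = [k for k in range(sk.n_nodes) if VOLUME.contains(sk.coords[k])]
    best = min(inside, key=lambda k: dist[k])
    assert entry == int(sk.node_ids[best])
    assert lc.cortex_neurite_length(sk, VOLUME) == pytest.approx(dist[best])


def test_entry_none_outside():
    sk = chain_skeleton([[0, 0, 0], [100, 0, 0]])
    assert lc.neuropil_entry(sk, VOLUME) is None
    assert lc.cortex_neurite_length(sk, VOLUME) is None


def test_cortex_length_matches_graph_oracle(rng):
    import networkx as nx

    sk = random_tree_skeleton(rng, n_nodes=40)
    vol = lc.NeuropilVolume(
        "axis_aligned_box", {"min": [0, -1e6, -1e6], "max": [1e7, 1e6, 1e6]}
    )
    g = nx.Graph()
    for k in range(sk.n_nodes):
        p = sk.parent_index[k]
        if p >= 0:
            g.add_edge(k, p, weight=float(np.linalg.norm(sk.coords[k] - sk.coords[p])))
    lengths = nx.single_source_dijkstra_path_length(g, sk.root_index)
    inside = [k for k in range(sk.n_nodes) if vol.contains(sk.coords[k])]
    expected = min(lengths[k] for k in inside)
    assert lc.cortex_neurite_length(sk, vol) == pytest.approx(expected)


def test_cortex_length_invariant_to_reindexing_and_subdivision():
    pts = [[0, 0, 0], [1000, 0, 0], [2000, 0, 0], [4000, 0, 0]]
    sk = chain_skeleton(pts)
    base = lc.cortex_neurite_length(sk, VOLUME)

    # re-index nodes (reverse ids)
    sk2 = lc.Skeleton(
        "r",
        node_ids=np.array([9, 7, 5, 3]),
        parent_ids=np.array([-1, 9, 7, 5]),
        coords=np.array(pts, dtype=float),
        radii=np.full(4, 100.0),
    )
    assert lc.cortex_neurite_length(sk2, VOLUME) == pytest.approx(base)

    # subdivide an edge with a collinear midpoint
    pts3 = [[0, 0, 0], [500, 0, 0], [1000, 0, 0], [2000, 0, 0], [4000, 0, 0]]
    assert lc.cortex_neurite_length(chain_skeleton(pts3), VOLUME) == pytest.approx(base)


# ---------------------------------------------------------------------------
# Temporal binning
# ---------------------------------------------------------------------------


def test_bilateral_mean_length():
    assert lc.bilateral_mean_length(3000, 3000) == 3000
    assert lc.bilateral_mean_length(2000, 4000) == 3000
    with pytest.warns(UserWarning):
        assert lc.bilateral_mean_length(None, 4000) == 4000
    assert lc.bilateral_mean_length(None, None) is None


def test_fit_temporal_bins_hand_computed():
    bins = lc.fit_temporal_bins([10, 12, 14], [30, 34, 38])
    assert bins.t1 == pytest.approx(14.0)
    assert bins.t2 == pytest.approx(30.0)
    assert bins.t3 == pytest.approx(34.0)


def test_fit_temporal_bins_zero_sd_and_near_boundary():
    assert lc.fit_temporal_bins([5, 5, 5], [30, 34, 38]).t1 == pytest.approx(5.0)
    # hand arithmetic: t1 = 25 + 7.0711 = 32.07 > t2 = 29 - 1.414 = 27.59
    with pytest.raises(ValueError):
        lc.fit_temporal_bins([20, 30], [28, 30])
    # flipped spread keeps the ordering valid: t1 = 26.41 < t2 = 27.59
    bins = lc.fit_temporal_bins([24, 26], [28, 30])
    assert bins.t1 == pytest.approx(25 + np.sqrt(2), abs=1e-6)


def test_assign_temporal_group_examples_and_boundary():
    bins = lc.fit_temporal_bins([10, 12, 14], [30, 34, 38])
    assert lc.assign_temporal_group(13, bins) == 1
    assert lc.assign_temporal_group(20, bins) == 2
    assert lc.assign_temporal_group(32, bins) == 3
    assert lc.assign_temporal_group(40, bins) == 4
    assert lc.assign_temporal_group(bins.t1, bins) == 2  # boundary owned by group 2
    assert lc.assign_temporal_group(bins.t2, bins) == 2
    assert lc.assign_temporal_group(bins.t3, bins) == 3


@given(st.floats(0, 50), st.floats(0, 50))
def test_assign_temporal_group_monotone(l1, l2):
    bins = lc.fit_temporal_bins([10, 12, 14], [30, 34, 38])
    g1, g2 = lc.assign_temporal_group(l1, bins), lc.assign_temporal_group(l2, bins)
    if l1 < l2:
        assert g1 <= g2


# ---------------------------------------------------------------------------
# Dotprops and morphological similarity
# ---------------------------------------------------------------------------


def test_dotprops_straight_segment():
    sk = chain_skeleton([[0, 0, 0], [10000, 0, 0]])
    dp = lc.to_dotprops(sk, spacing=1000)
    assert len(dp) == 11
    assert np.allclose(np.abs(dp.tangents @ np.array([1.0, 0, 0])), 1.0, atol=1e-9)


def test_dotprops_two_node_minimum():
    sk = chain_skeleton([[0, 0, 0], [0, 0, 500]])
    dp = lc.to_dotprops(sk, spacing=1000)
    assert len(dp) >= 2
    assert np.allclose(np.abs(dp.tangents @ np.array([0, 0, 1.0])), 1.0, atol=1e-9)


def test_dotprops_corner_tangent_intermediate():
    sk = chain_skeleton([[0, 0, 0], [5000, 0, 0], [5000, 5000, 0]])
    dp = lc.to_dotprops(sk, spacing=1000, k=5)
    corner = np.argmin(np.linalg.norm(dp.points - np.array([5000, 0, 0]), axis=1))
    t = dp.tangents[corner]
    assert 0.05 < abs(t[0]) < 0.99 and 0.05 < abs(t[1]) < 0.99


def test_morph_similarity_self_orthogonal_and_kernel_value():
    pts = np.array([[0.0, 0, 0], [1000, 0, 0], [2000, 0, 0]])
    tx = np.tile([1.0, 0, 0], (3, 1))
    ty = np.tile([0.0, 1, 0], (3, 1))
    dpx = lc.DotProps(pts, tx, 1000, 2)
    assert lc.morph_similarity(dpx, dpx) == pytest.approx(1.0)
    dpy = lc.DotProps(pts, ty, 1000, 2)
    assert lc.morph_similarity(dpx, dpy) == pytest.approx(0.0, abs=1e-12)

    a = lc.DotProps([[0.0, 0, 0]], [[1.0, 0, 0]], 1000, 1)
    b = lc.DotProps([[2000.0, 0, 0]], [[1.0, 0, 0]], 1000, 1)
    assert lc.morph_similarity(a, b, sigma_n=2000) == pytest.approx(np.exp(-0.5))


def test_morph_similarity_rigid_motion_invariance(rng):
    sk1 = random_tree_skeleton(rng, 20, "a")
    sk2 = random_tree_skeleton(rng, 20, "b")
    d1, d2 = lc.to_dotprops(sk1), lc.to_dotprops(sk2)
    base = lc.morph_similarity(d1, d2)

    theta = 0.7
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    shift = np.array([500.0, -300.0, 800.0])

    def moved(dp):
        return lc.DotProps(dp.points @ R.T + shift, dp.tangents @ R.T, dp.spacing, dp.k_neighbors)

    assert lc.morph_similarity(moved(d1), moved(d2)) == pytest.approx(base, abs=1e-9)


def test_cluster_two_separated_groups_stable_over_cutoffs(rng):
    # two morphological groups: jittered copies of a shared template path,
    # group centroids far apart relative to the jitter
    def group(center):
        template = center + np.cumsum(rng.normal(0, 1500, (8, 3)), axis=0)
        return [
            lc.to_dotprops(chain_skeleton(template + rng.normal(0, 200, (8, 3))))
            for _ in range(5)
        ]

    dps = group(np.zeros(3)) + group(np.array([50000.0, 0, 0]))
    S = np.array([[lc.morph_similarity(a, b) for b in dps] for a in dps])
    for cutoff in (0.5, 0.7, 0.9, 0.95):
        labels = lc.cluster_hemilineages(S, height_cutoff=cutoff)
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1


def test_cluster_degenerate_cases():
    S = np.ones((4, 4))
    assert len(set(lc.cluster_hemilineages(S))) == 1  # identical neurons
    assert list(lc.cluster_hemilineages(np.array([[1.0]]))) == [1]
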
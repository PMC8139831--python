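import numpy as np
import pandas as pd
import pytest

import lineagecircuits as lc
from lineagecircuits.connectivity import CohortGrouping, grouping_pair_values

from oracles import bfs_distances


def matrix_from(counts, ids=None):
    counts = np.asarray(counts)
    ids = ids or [f"n{i}" for i in range(counts.shape[0])]
    return lc.ConnectivityMatrix(ids, counts)


# ---------------------------------------------------------------------------
# Premotor / postsensory classification
# ---------------------------------------------------------------------------


def test_premotor_strict_threshold_per_partner():
    # i0: 4 synapses onto one motor neuron -> premotor
    # i1: exactly 3 -> not premotor (strict >)
    # i2: 2+2 across two motor neurons -> not premotor under per-partner rule
    counts5 = np.zeros((5, 5), dtype=int)
    counts5[0, 3] = 4
    counts5[1, 3] = 3
    counts5[2, 3] = 2
    counts5[2, 4] = 2
    m = matrix_from(counts5, ["i0", "i1", "i2", "m1", "m2"])
    flags = lc.classify_premotor_postsensory(m, motor_ids=["m1", "m2"], sensory_ids=[])
    assert flags.loc["i0", "premotor"]
    assert not flags.loc["i1", "premotor"]
    assert not flags.loc["i2", "premotor"]
    agg = lc.classify_premotor_postsensory(
        m, motor_ids=["m1", "m2"], sensory_ids=[], per_partner=False
    )
    assert agg.loc["i2", "premotor"]  # aggregate variant: 2 + 2 > 3


def test_postsensory_symmetric():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 2] = 5  # s0 -> i0
    m = matrix_from(counts, ["s0", "i1", "i0"])
    flags = lc.classify_premotor_postsensory(m, motor_ids=[], sensory_ids=["s0"])
    assert flags.loc["i0", "postsensory"]
    assert not flags.loc["i1", "postsensory"]


# ---------------------------------------------------------------------------
# Group input/output fractions
# ---------------------------------------------------------------------------


def test_group_io_fractions_arithmetic():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 1] = 3
    counts[0, 2] = 7
    m = matrix_from(counts, ["s", "a", "b", "c"])
    out = lc.group_io_fractions(m, ["s"], {"A": ["a"], "B": ["b"]})
    frac = out.set_index("group")["fraction"]
    assert frac["A"] == pytest.approx(0.3)
    assert frac["B"] == pytest.approx(0.7)

    only = lc.group_io_fractions(m, ["s"], {"all": ["a", "b", "c"]})
    assert only["fraction"].iloc[0] == pytest.approx(1.0)

    with pytest.warns(UserWarning, match="zero total"):
        zero = lc.group_io_fractions(m, ["c"], {"A": ["a"]})
    assert np.isnan(zero["fraction"].iloc[0])


def test_group_io_fractions_inputs_direction():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 2] = 2
    counts[1, 2] = 6
    m = matrix_from(counts, ["a", "b", "mtr"])
    inp = lc.group_io_fractions(m, ["mtr"], {"A": ["a"], "B": ["b"]}, direction="inputs")
    frac = inp.set_index("group")["fraction"]
    assert frac["A"] == pytest.approx(0.25)
    assert frac["B"] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Cosine connectivity similarity
# ---------------------------------------------------------------------------


def test_connectivity_similarity_closed_forms():
    mat = np.array(
        [
            [0, 1, 1, 0],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
            [0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    b = lc.BinaryConnectivity([f"n{i}" for i in range(4)], mat, threshold=1)
    sim = lc.connectivity_similarity(b, axis="outputs")
    assert sim.iloc[0, 1] == pytest.approx(1.0)   # identical rows
    assert sim.iloc[0, 2] == pytest.approx(0.5)   # (1,1,0)x(1,0,1) -> 1/2
    assert sim.iloc[0, 3] == 0.0                  # zero vector -> flagged 0
    assert "n3" in sim.attrs["zero_vectors"]

    disjoint = lc.BinaryConnectivity(
        ["a", "b"], np.array([[0, 1], [1, 0]], dtype=np.int8), threshold=1
    )
    s2 = lc.connectivity_similarity(disjoint, axis="outputs")
    assert s2.iloc[0, 1] == pytest.approx(0.0)


def test_connectivity_similarity_inputs_axis():
    mat = np.zeros((3, 3), dtype=np.int8)
    mat[0, 1] = mat[0, 2] = 1  # n1 and n2 share their only input
    b = lc.BinaryConnectivity(["n0", "n1", "n2"], mat, threshold=1)
    sim = lc.connectivity_similarity(b, axis="inputs")
    assert sim.loc["n1", "n2"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Network distance
# ---------------------------------------------------------------------------


def test_network_distance_direction_blind_rules():
    ids = ["a", "b", "c", "d"]
    mat = np.zeros((4, 4), dtype=np.int8)
    mat[0, 1] = 1  # a -> b
    b = lc.BinaryConnectivity(ids, mat, threshold=1)
    d = lc.network_distance(b)
    assert d.loc["a", "b"] == 1

    mat2 = np.zeros((4, 4), dtype=np.int8)
    mat2[0, 2] = 1  # a -> c
    mat2[1, 2] = 1  # b -> c: shared output => distance(a, b) = 2
    d2 = lc.network_distance(lc.BinaryConnectivity(ids, mat2, threshold=1))
    assert d2.loc["a", "b"] == 2
    assert np.isinf(d2.loc["a", "d"])

    chain = np.zeros((4, 4), dtype=np.int8)
    chain[0, 1] = chain[1, 2] = chain[2, 3] = 1
    d3 = lc.network_distance(lc.BinaryConnectivity(ids, chain, threshold=1))
    assert d3.loc["a", "d"] == 3


def test_network_distance_matches_bfs_oracle_and_metric_axioms(rng):
    n = 60
    mat = (rng.random((n, n)) < 0.04).astype(np.int8)
    np.fill_diagonal(mat, 0)
    b = lc.BinaryConnectivity([f"n{i}" for i in range(n)], mat, threshold=1)
    d = lc.network_distance(b).to_numpy()
    expected = bfs_distances(mat)
    assert np.array_equal(d, expected)
    assert np.allclose(d, d.T)
    # distance-1 pairs are exactly the undirected support
    support = ((mat + mat.T) > 0)
    assert np.array_equal(d == 1, support & (d == 1))
    assert np.array_equal((d == 1), support)
    # triangle inequality on finite entries
    finite = np.isfinite(d)
    for i in range(0, n, 7):
        for j in range(0, n, 7):
            for k in range(0, n, 7):
                if finite[i, j] and finite[j, k]:
                    assert d[i, k] <= d[i, j] + d[j, k]


# ---------------------------------------------------------------------------
# Cohort comparisons
# ---------------------------------------------------------------------------


def _metric_with_pair_values(cohorts, pair_values):
    """Build a symmetric metric matrix whose within-cohort pairs carry the
    requested values (cohorts of size 3 -> 3 pairs each)."""
    ids = [i for members in cohorts.values() for i in members]
    M = pd.DataFrame(0.0, index=ids, columns=ids)
    for members, values in zip(cohorts.values(), pair_values):
        pairs = [(0, 1), (0, 2), (1, 2)]
        for (x, y), v in zip(pairs, values):
            M.loc[members[x], members[y]] = v
            M.loc[members[y], members[x]] = v
    return M


def test_cohort_comparison_exact_ranksum_p():
    g1 = CohortGrouping("hemilineage_temporal", {"c1": ["a1", "a2", "a3"]})
    g2 = CohortGrouping("unrelated_same_hemisegment", {"u1": ["b1", "b2", "b3"]})
    M = _metric_with_pair_values(
        {"c1": ["a1", "a2", "a3"], "u1": ["b1", "b2", "b3"]},
        [[1, 2, 3], [101, 102, 103]],
    )
    res = lc.cohort_comparison(M, [g1, g2])
    row = res.tests.iloc[0]
    assert row["p"] == pytest.approx(0.1)  # exact enumeration of 20 assignments
    assert res.summary.set_index("grouping").loc["hemilineage_temporal", "n_pairs"] == 3


def test_cohort_comparison_identical_distributions_ks_zero():
    g1 = CohortGrouping("hemilineage_temporal", {"c1": ["a1", "a2", "a3"]})
    g2 = CohortGrouping("hemilineage_only", {"u1": ["b1", "b2", "b3"]})
    M = _metric_with_pair_values(
        {"c1": ["a1", "a2", "a3"], "u1": ["b1", "b2", "b3"]},
        [[1, 2, 3], [1, 2, 3]],
    )
    res = lc.cohort_comparison(M, [g1, g2])
    assert res.tests.iloc[0]["ks_statistic"] == pytest.approx(0.0)


def test_singleton_cohorts_contribute_no_pairs():
    g = CohortGrouping("hemilineage_temporal", {"c1": ["a1"], "c2": ["b1", "b2"]})
    M = pd.DataFrame(
        [[0, 1, 2], [1, 0, 3], [2, 3, 0]],
        index=["a1", "b1", "b2"],
        columns=["a1", "b1", "b2"],
        dtype=float,
    )
    vals = grouping_pair_values(M, g)
    assert vals.tolist() == [3.0]


def test_standard_groupings_structure_and_exclusions(small_connectome):
    ann = small_connectome.annotations
    groupings = lc.build_standard_groupings(ann, rng=0)
    kinds = [g.kind for g in groupings]
    assert kinds == [
        "unrelated_same_hemisegment",
        "temporal_only",
        "hemilineage_only",
        "hemilineage_temporal",
    ]
    by_kind = dict(zip(kinds, groupings))

    # hemilineage_only pools exclude same-temporal pairs: a hemilineage with
    # T temporal groups of n neurons has C(nT,2) - T*C(n,2) eligible pairs
    hl = by_kind["hemilineage_only"]
    one = {k: v for k, v in list(hl.members.items())[:1]}
    vals = grouping_pair_values(
        pd.DataFrame(
            1.0,
            index=ann["neuron_id"],
            columns=ann["neuron_id"],
        ),
        CohortGrouping("hemilineage_only", one),
        annotations=ann,
    )
    n, T = 3, 2
    assert len(vals) == (n * T) * (n * T - 1) // 2 - T * (n * (n - 1) // 2)

    # within a grouping, cohorts are disjoint
    with pytest.raises(ValueError, match="disjoint"):
        CohortGrouping("temporal_only", {"a": ["x", "y"], "b": ["y", "z"]})
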
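import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import lineagecircuits as lc
from lineagecircuits.core import ConsistencyError, FormatError

from conftest import random_tree_skeleton
from oracles import brute_connectivity


# ---------------------------------------------------------------------------
# SWC skeletons
# ---------------------------------------------------------------------------


def test_read_swc_minimal_single_node(tmp_path):
    p = tmp_path / "one.swc"
    p.write_text("1 1 0 0 0 500 -1\n")
    sk = lc.read_swc(p)
    assert sk.n_nodes == 1
    assert sk.root == 1
    assert sk.cable_length() == 0.0


def test_read_swc_chain_cable_length(tmp_path):
    p = tmp_path / "chain.swc"
    p.write_text(
        "1 0 0 0 0 100 -1\n"
        "2 0 0 0 1000 100 1\n"
        "3 0 0 0 2500 100 2\n"
    )
    sk = lc.read_swc(p)
    assert sk.cable_length() == pytest.approx(2500.0)


@pytest.mark.parametrize(
    "content,match",
    [
        ("1 0 0 0 0 1 -1\n3 0 1 1 1 1 3\n", "cycle"),          # self-parent
        ("1 0 0 0 0 1 -1\n2 0 1 1 1 1 -1\n", "one root"),       # two roots
        ("1 0 0 0 zz 1 -1\n", r"bad\.swc:1"),                   # non-numeric w/ lineno
        ("1 0 0 0 0 1 -1\n2 0 1 1 1 1 9\n", "missing parent"),  # dangling parent
    ],
)
def test_read_swc_format_errors(tmp_path, content, match):
    p = tmp_path / "bad.swc"
    p.write_text(content)
    with pytest.raises(FormatError, match=match):
        lc.read_swc(p)


def test_swc_round_trip(tmp_path, rng):
    sk = random_tree_skeleton(rng, n_nodes=25)
    lc.write_swc(sk, tmp_path / "t.swc")
    back = lc.read_swc(tmp_path / "t.swc", neuron_id=sk.neuron_id)
    assert np.array_equal(back.node_ids, sk.node_ids)
    assert np.array_equal(back.parent_ids, sk.parent_ids)
    assert np.allclose(back.coords, sk.coords, atol=1e-3)


# ---------------------------------------------------------------------------
# Connector tables
# ---------------------------------------------------------------------------


def _connector_frame(rows):
    return pd.DataFrame(rows, columns=lc.core.CONNECTOR_COLUMNS)


def test_connector_grouping_polyadic(tmp_path):
    rows = [
        ("c1", "A", 0, 0, 0, p, 1, 1, 1) for p in ("B", "C", "D")
    ] + [("c2", "A", 5, 5, 5, "B", 2, 2, 2)]
    f = tmp_path / "c.csv"
    _connector_frame(rows).to_csv(f, index=False)
    connectors = lc.read_connector_table(f)
    assert len(connectors) == 2
    assert connectors[0].n_partners == 3
    assert [nid for nid, _ in connectors[0].post_partners] == ["B", "C", "D"]


def test_connector_conflicting_pre_location(tmp_path):
    rows = [("c1", "A", 0, 0, 0, "B", 1, 1, 1), ("c1", "A", 9, 0, 0, "C", 1, 1, 1)]
    f = tmp_path / "c.csv"
    _connector_frame(rows).to_csv(f, index=False)
    with pytest.raises(ConsistencyError, match="conflicting"):
        lc.read_connector_table(f)


def test_autapse_rejected_at_construction_and_dropped_at_read(tmp_path, caplog):
    with pytest.raises(ConsistencyError, match="autapse"):
        lc.Connector("c", "A", np.zeros(3), [("A", np.ones(3))])
    rows = [("c1", "A", 0, 0, 0, "A", 1, 1, 1), ("c1", "A", 0, 0, 0, "B", 1, 1, 1)]
    f = tmp_path / "c.csv"
    _connector_frame(rows).to_csv(f, index=False)
    with caplog.at_level("WARNING"):
        connectors = lc.read_connector_table(f)
    assert len(connectors) == 1
    assert connectors[0].n_partners == 1
    assert "autaptic" in caplog.text


def test_connector_round_trip(tmp_path, rng):
    connectors = [
        lc.Connector(
            f"c{i}",
            "A",
            rng.uniform(0, 100, 3),
            [("B", rng.uniform(0, 100, 3)), ("C", rng.uniform(0, 100, 3))],
        )
        for i in range(5)
    ]
    lc.write_connector_table(connectors, tmp_path / "c.csv")
    back = lc.read_connector_table(tmp_path / "c.csv")
    assert len(back) == 5
    for orig, loaded in zip(connectors, back):
        assert loaded.connector_id == orig.connector_id
        assert np.allclose(loaded.pre_location, orig.pre_location)
        assert [n for n, _ in loaded.post_partners] == [n for n, _ in orig.post_partners]


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------


def test_build_connectivity_polyadic_counts_once_per_partner():
    c = lc.Connector("c1", "A", np.zeros(3), [("B", np.ones(3)), ("B", np.ones(3)), ("C", np.ones(3))])
    m = lc.build_connectivity([c], ["A", "B", "C"])
    assert m.counts[0, 1] == 2
    assert m.counts[0, 2] == 1
    assert m.counts.sum() == 3


def test_build_connectivity_empty_and_errors():
    m = lc.build_connectivity([], ["A", "B"])
    assert m.counts.sum() == 0
    with pytest.raises(ValueError):
        lc.build_connectivity([], [])


def test_build_connectivity_matches_brute_force(rng):
    ids = [f"n{i}" for i in range(20)]
    connectors = []
    for k in range(200):
        pre = ids[rng.integers(0, 20)]
        partners = [
            (ids[int(j)], rng.uniform(0, 10, 3))
            for j in rng.integers(0, 20, size=rng.integers(1, 4))
            if ids[int(j)] != pre
        ]
        if not partners:
            continue
        connectors.append(lc.Connector(f"c{k}", pre, rng.uniform(0, 10, 3), partners))
    m = lc.build_connectivity(connectors, ids)
    assert np.array_equal(m.counts, brute_connectivity(connectors, ids))
    assert m.counts.sum() == sum(c.n_partners for c in connectors)


def test_binarize_examples_and_oracle(rng):
    ids = ["a", "b"]
    counts = np.array([[0, 2], [3, 0]])
    m = lc.ConnectivityMatrix(ids, counts)
    b2 = lc.binarize(m, 2)
    assert np.array_equal(b2.matrix, counts >= 2)
    assert b2.threshold == 2
    assert np.array_equal(lc.binarize(m, 1).matrix, counts >= 1)
    big = rng.integers(0, 6, (10, 10))
    np.fill_diagonal(big, 0)
    mm = lc.ConnectivityMatrix([f"n{i}" for i in range(10)], big)
    assert np.array_equal(lc.binarize(mm, 3).matrix, (big >= 3).astype(int))
    with pytest.raises(ValueError):
        lc.binarize(m, 0)


@given(st.integers(min_value=1, max_value=8))
def test_binarize_monotone_in_threshold(threshold):
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 6, (8, 8))
    np.fill_diagonal(counts, 0)
    m = lc.ConnectivityMatrix([f"n{i}" for i in range(8)], counts)
    low = lc.binarize(m, threshold).matrix
    high = lc.binarize(m, threshold + 1).matrix
    assert not np.any(high > low)  # raising the threshold never adds edges


def test_diagonal_must_be_zero():
    with pytest.raises(ConsistencyError):
        lc.ConnectivityMatrix(["a", "b"], np.array([[1, 0], [0, 0]]))


# ---------------------------------------------------------------------------
# Annotations and neuropil volumes
# ---------------------------------------------------------------------------


def test_homolog_invariant_enforced(tmp_path):
    rows = [
        {"neuron_id": "x-L", "lineage": "NB1", "hemilineage": "dorsal",
         "temporal_group": 1, "hemisegment": "left", "homolog_id": "x",
         "cell_class": "interneuron"},
        {"neuron_id": "x-R", "lineage": "NB2", "hemilineage": "dorsal",
         "temporal_group": 1, "hemisegment": "right", "homolog_id": "x",
         "cell_class": "interneuron"},
    ]
    f = tmp_path / "ann.csv"
    pd.DataFrame(rows).to_csv(f, index=False)
    with pytest.raises(ConsistencyError, match="labels differ"):
        lc.read_annotation_table(f)


def test_neuropil_volume_contains_and_json(tmp_path):
    box = lc.NeuropilVolume("axis_aligned_box", {"min": [0, 0, 0], "max": [10, 10, 10]})
    assert box.contains([5, 5, 5])
    assert box.contains([0, 0, 0])  # inclusive boundary
    assert not box.contains([11, 5, 5])
    ell = lc.NeuropilVolume("ellipsoid", {"center": [0, 0, 0], "radii": [10, 5, 5]})
    assert ell.contains([9, 0, 0]) and not ell.contains([0, 6, 0])
    lc.write_neuropil_volume(box, tmp_path / "v.json")
    back = lc.read_neuropil_volume(tmp_path / "v.json")
    assert back.kind == box.kind and back.params == box.params
    pts = np.array([[5, 5, 5], [20, 0, 0]])
    assert np.array_equal(back.contains(pts), box.contains(pts))
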
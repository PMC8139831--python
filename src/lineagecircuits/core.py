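"""Core data model and file formats.

Shared containers for connectome analyses: rooted skeleton trees (soma at
the root), polyadic synaptic connectors (one presynaptic site with one or
more postsynaptic partner sites), per-neuron developmental annotations, a
neuron-by-neuron synaptic contact-count matrix, and bounded neuropil
volumes.

Units and axes
--------------
All coordinates, radii and length parameters are nanometres.  The axis
convention is fixed: x = mediolateral, y = dorsoventral (dorsal = +y),
z = anteroposterior.

Interchange formats are plain text: 7-column SWC for skeletons, UTF-8 CSV
with a header row for connector and annotation tables, JSON for neuropil
volumes and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEMILINEAGES = ("dorsal", "ventral", "glial", "unassigned")
CELL_CLASSES = ("interneuron", "motor", "sensory")
HEMISEGMENTS = ("left", "right")

ANNOTATION_COLUMNS = [
    "neuron_id",
    "lineage",
    "hemilineage",
    "temporal_group",
    "hemisegment",
    "homolog_id",
    "cell_class",
]

CONNECTOR_COLUMNS = [
    "connector_id",
    "pre_neuron",
    "pre_x",
    "pre_y",
    "pre_z",
    "post_neuron",
    "post_x",
    "post_y",
    "post_z",
]


class FormatError(ValueError):
    """A file violates its declared format (bad SWC tree, bad CSV schema)."""


class ConsistencyError(ValueError):
    """Structurally valid input carries mutually inconsistent records."""


class ConfigError(ValueError):
    """A configuration value is outside its admissible range."""


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------


@dataclass
class Skeleton:
    """A neuron skeleton: a rooted tree of 3D nodes with the soma at the root.

    Parameters
    ----------
    neuron_id
        Identifier of the neuron the skeleton belongs to.
    node_ids
        Integer node identifiers, in file order.
    parent_ids
        Parent node identifier per node; ``-1`` marks the root (soma).
    coords
        ``(n, 3)`` array of node positions in nm.
    radii
        Node radii in nm.
    """

    neuron_id: str
    node_ids: np.ndarray
    parent_ids: np.ndarray
    coords: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = self.node_ids.size
        if n == 0:
            raise FormatError("skeleton has no nodes")
        if self.coords.shape != (n, 3):
            raise FormatError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates")
        if np.unique(self.node_ids).size != n:
            raise FormatError("duplicate node ids")
        roots = np.flatnonzero(self.parent_ids == -1)
        if roots.size != 1:
            raise FormatError(f"expected exactly one root, found {roots.size}")
        self._root_index = int(roots[0])
        index = {int(i): k for k, i in enumerate(self.node_ids)}
        self._index = index
        pidx = np.full(n, -1, dtype=np.int64)
        for k, p in enumerate(self.parent_ids):
            if p == -1:
                continue
            if int(p) not in index:
                raise FormatError(f"node {self.node_ids[k]} references missing parent {p}")
            pidx[k] = index[int(p)]
        self._parent_index = pidx
        # Reachability from the root doubles as the cycle check: a parent
        # relation on n nodes with one root is a tree iff all nodes are
        # reachable going rootward without revisiting.
        children: list[list[int]] = [[] for _ in range(n)]
        for k, p in enumerate(pidx):
            if p >= 0:
                children[p].append(k)
        seen = np.zeros(n, dtype=bool)
        stack = [self._root_index]
        while stack:
            k = stack.pop()
            seen[k] = True
            stack.extend(children[k])
        if not seen.all():
            raise FormatError("parent links contain a cycle or disconnected component")
        self._children = children

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    @property
    def root(self) -> int:
        """Node id of the soma node."""
        return int(self.node_ids[self._root_index])

    @property
    def root_index(self) -> int:
        return self._root_index

    @property
    def parent_index(self) -> np.ndarray:
        """Positional index of each node's parent (-1 at the root)."""
        return self._parent_index

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def children_of(self, index: int) -> list[int]:
        return self._children[index]

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge to each node's parent (0 at the root)."""
        out = np.zeros(self.n_nodes)
        has = self._parent_index >= 0
        out[has] = np.linalg.norm(
            self.coords[has] - self.coords[self._parent_index[has]], axis=1
        )
        return out

    def cable_length(self) -> float:
        """Total cable length in nm (sum of Euclidean edge lengths)."""
        return float(self.edge_lengths().sum())

    def distances_to_root(self) -> np.ndarray:
        """Geodesic (along-the-tree) distance from every node to the root."""
        el = self.edge_lengths()
        dist = np.zeros(self.n_nodes)
        stack = [self._root_index]
        while stack:
            k = stack.pop()
            for c in self._children[k]:
                dist[c] = dist[k] + el[c]
                stack.append(c)
        return dist

    def subset(self, keep: np.ndarray) -> "Skeleton":
        """Restrict to a node mask that must stay root-connected."""
        keep = np.asarray(keep, dtype=bool)
        if not keep[self._root_index]:
            raise ValueError("subset must retain the root")
        kept_ids = set(self.node_ids[keep].tolist())
        parents = self.parent_ids[keep].copy()
        for i, p in enumerate(parents):
            if p != -1 and int(p) not in kept_ids:
                raise ValueError("subset is not rootward-closed")
        return Skeleton(
            neuron_id=self.neuron_id,
            node_ids=self.node_ids[keep].copy(),
            parent_ids=parents,
            coords=self.coords[keep].copy(),
            radii=self.radii[keep].copy(),
        )


def read_swc(path: str | Path, neuron_id: str | None = None) -> Skeleton:
    """Read a 7-column SWC file (whitespace separated, parent -1 = root).

    Coordinates and radii are interpreted in nm.  Node order is preserved.

    Raises
    ------
    FormatError
        On non-numeric fields (with the offending line number), multiple
        roots, missing parents or cycles.
    """
    path = Path(path)
    node_ids, parents, coords, radii = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}")
            try:
                nid = int(fields[0])
                xyz = [float(fields[2]), float(fields[3]), float(fields[4])]
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
            node_ids.append(nid)
            parents.append(parent)
            coords.append(xyz)
            radii.append(radius)
    if not node_ids:
        raise FormatError(f"{path.name}: empty SWC file")
    return Skeleton(
        neuron_id=neuron_id if neuron_id is not None else path.stem,
        node_ids=np.array(node_ids),
        parent_ids=np.array(parents),
        coords=np.array(coords),
        radii=np.array(radii),
    )


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    """Write a Skeleton as 7-column SWC (structure label 0, nm units)."""
    with open(path, "w") as fh:
        fh.write(f"# SWC export of neuron {skeleton.neuron_id}; units nm\n")
        for k in range(skeleton.n_nodes):
            x, y, z = skeleton.coords[k]
            fh.write(
                f"{skeleton.node_ids[k]} 0 {x:.3f} {y:.3f} {z:.3f} "
                f"{skeleton.radii[k]:.3f} {skeleton.parent_ids[k]}\n"
            )


# ---------------------------------------------------------------------------
# Connectors (polyadic synapses)
# ---------------------------------------------------------------------------


@dataclass
class Connector:
    """One presynaptic site with >=1 postsynaptic partner sites.

    Polyadic synapses are represented once and counted once per partner in
    downstream connectivity tallies.
    """

    connector_id: str
    pre_neuron: str
    pre_location: np.ndarray
    post_partners: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.pre_location = np.asarray(self.pre_location, dtype=float).reshape(3)
        self.post_partners = [
            (str(nid), np.asarray(loc, dtype=float).reshape(3)) for nid, loc in self.post_partners
        ]
        if len(self.post_partners) < 1:
            raise FormatError(f"connector {self.connector_id}: no postsynaptic partners")
        if any(nid == str(self.pre_neuron) for nid, _ in self.post_partners):
            raise ConsistencyError(
                f"connector {self.connector_id}: autapse (pre neuron among its partners)"
            )

    @property
    def n_partners(self) -> int:
        return len(self.post_partners)


def read_connector_table(path: str | Path) -> list[Connector]:
    """Read a connector CSV (one row per (connector, post-partner) pair).

    Rows sharing ``connector_id`` are merged into one polyadic
    :class:`Connector`; row order within a connector is preserved.  Autapse
    partner rows (post neuron equal to the presynaptic neuron) are dropped
    with a logged count rather than silently kept.

    Raises
    ------
    FormatError
        Missing columns or missing partner fields.
    ConsistencyError
        Conflicting presynaptic neuron/location for one connector id.
    """
    df = pd.read_csv(path, dtype={"connector_id": str, "pre_neuron": str, "post_neuron": str})
    missing = [c for c in CONNECTOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"connector table missing columns: {missing}")
    if df[["post_neuron", "post_x", "post_y", "post_z"]].isna().any(axis=None):
        raise FormatError("connector table has rows without a postsynaptic partner")
    connectors: list[Connector] = []
    n_autapse = 0
    for cid, grp in df.groupby("connector_id", sort=False):
        pre_ids = grp["pre_neuron"].unique()
        pre_locs = grp[["pre_x", "pre_y", "pre_z"]].drop_duplicates()
        if len(pre_ids) != 1 or len(pre_locs) != 1:
            raise ConsistencyError(f"connector {cid}: conflicting presynaptic records")
        pre = str(pre_ids[0])
        partners = []
        for _, row in grp.iterrows():
            if str(row["post_neuron"]) == pre:
                n_autapse += 1
                continue
            partners.append((str(row["post_neuron"]), row[["post_x", "post_y", "post_z"]].to_numpy(float)))
        if not partners:
            logger.warning("connector %s dropped: only autaptic partners", cid)
            continue
        connectors.append(
            Connector(
                connector_id=str(cid),
                pre_neuron=pre,
                pre_location=pre_locs.to_numpy(float)[0],
                post_partners=partners,
            )
        )
    if n_autapse:
        logger.warning("dropped %d autaptic partner rows", n_autapse)
    return connectors


def write_connector_table(connectors: Iterable[Connector], path: str | Path) -> None:
    rows = []
    for c in connectors:
        for nid, loc in c.post_partners:
            rows.append(
                {
                    "connector_id": c.connector_id,
                    "pre_neuron": c.pre_neuron,
                    "pre_x": c.pre_location[0],
                    "pre_y": c.pre_location[1],
                    "pre_z": c.pre_location[2],
                    "post_neuron": nid,
                    "post_x": loc[0],
                    "post_y": loc[1],
                    "post_z": loc[2],
                }
            )
    pd.DataFrame(rows, columns=CONNECTOR_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class NeuronAnnotation:
    """Developmental and functional labels for one neuron."""

    neuron_id: str
    lineage: str
    hemilineage: str = "unassigned"
    temporal_group: int | str = "unassigned"
    hemisegment: str = "left"
    homolog_id: str | None = None
    cell_class: str = "interneuron"

    def __post_init__(self) -> None:
        if self.hemilineage not in HEMILINEAGES:
            raise ConfigError(f"unknown hemilineage {self.hemilineage!r}")
        if self.cell_class not in CELL_CLASSES:
            raise ConfigError(f"unknown cell class {self.cell_class!r}")
        if self.hemisegment not in HEMISEGMENTS:
            raise ConfigError(f"unknown hemisegment {self.hemisegment!r}")
        if self.temporal_group != "unassigned":
            self.temporal_group = int(self.temporal_group)
            if self.temporal_group not in (1, 2, 3, 4):
                raise ConfigError("temporal_group must be 1-4 or 'unassigned'")


def annotations_to_frame(annotations: Iterable[NeuronAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame([vars(a) for a in annotations], columns=ANNOTATION_COLUMNS)
    return df.set_index("neuron_id", drop=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV into a neuron-indexed DataFrame and validate it.

    Homolog pairs must have opposite hemisegments and identical lineage and
    hemilineage labels.
    """
    df = pd.read_csv(path, dtype={"neuron_id": str, "homolog_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")

    def _coerce_group(v):
        try:
            return int(float(v))
        except (TypeError, ValueError):
            return "unassigned"

    df["temporal_group"] = df["temporal_group"].map(_coerce_group)
    df = df.set_index("neuron_id", drop=False)
    validate_homologs(df)
    return df


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index(drop=True).to_csv(path, index=False, columns=ANNOTATION_COLUMNS)


def validate_homologs(annotations: pd.DataFrame) -> None:
    """Check the bilateral homolog invariant on an annotation table."""
    with_h = annotations[annotations["homolog_id"].notna() & (annotations["homolog_id"] != "")]
    for hid, grp in with_h.groupby("homolog_id"):
        if len(grp) != 2:
            raise ConsistencyError(f"homolog id {hid}: expected a pair, found {len(grp)} neurons")
        if set(grp["hemisegment"]) != {"left", "right"}:
            raise ConsistencyError(f"homolog id {hid}: pair must span left and right")
        if grp["lineage"].nunique() != 1 or grp["hemilineage"].nunique() != 1:
            raise ConsistencyError(f"homolog id {hid}: lineage/hemilineage labels differ")


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Neuron x neuron synaptic contact counts.

    ``counts[i, j]`` is the number of (connector, post-partner) pairs from
    presynaptic neuron ``i`` onto postsynaptic neuron ``j``; the diagonal is
    zero by construction (autapses are rejected upstream).
    """

    neuron_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.neuron_ids = [str(i) for i in self.neuron_ids]
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.neuron_ids)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match neuron_ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diagonal(self.counts).any():
            raise ConsistencyError("diagonal of the contact-count matrix must be zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.neuron_ids, columns=self.neuron_ids)

    def binarize(self, threshold: int) -> "BinaryConnectivity":
        return binarize(self, threshold)


@dataclass
class BinaryConnectivity:
    """A thresholded connectivity matrix; remembers its threshold."""

    neuron_ids: list[str]
    matrix: np.ndarray
    threshold: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.neuron_ids, columns=self.neuron_ids)


def build_connectivity(
    connectors: Iterable[Connector], neuron_ids: Sequence[str]
) -> ConnectivityMatrix:
    """Tally a contact-count matrix from polyadic connectors.

    Each postsynaptic partner of a connector contributes one count, so a
    polyadic synapse is counted as many times as it has targets.  Connector
    endpoints naming neurons outside ``neuron_ids`` are dropped, with the
    dropped count logged (analyses typically cover a traced subset of a
    larger volume).
    """
    neuron_ids = [str(i) for i in neuron_ids]
    if not neuron_ids:
        raise ValueError("neuron_ids must be non-empty")
    index = {nid: k for k, nid in enumerate(neuron_ids)}
    counts = np.zeros((len(neuron_ids), len(neuron_ids)), dtype=np.int64)
    dropped = 0
    for c in connectors:
        i = index.get(str(c.pre_neuron))
        for nid, _ in c.post_partners:
            j = index.get(nid)
            if i is None or j is None:
                dropped += 1
                continue
            counts[i, j] += 1
    if dropped:
        logger.info("build_connectivity: dropped %d contacts naming unknown neurons", dropped)
    return ConnectivityMatrix(neuron_ids=neuron_ids, counts=counts)


def binarize(matrix: ConnectivityMatrix, threshold: int) -> BinaryConnectivity:
    """Binarize contact counts at ``threshold`` (entry 1 iff count >= threshold)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return BinaryConnectivity(
        neuron_ids=list(matrix.neuron_ids),
        matrix=(matrix.counts >= threshold).astype(np.int8),
        threshold=int(threshold),
    )


# ---------------------------------------------------------------------------
# Neuropil volumes
# ---------------------------------------------------------------------------


@dataclass
class NeuropilVolume:
    """A bounded region of neuropil with a deterministic containment test.

    kinds
    -----
    ``axis_aligned_box``: params ``{"min": [x,y,z], "max": [x,y,z]}``
    (inclusive bounds); ``ellipsoid``: params ``{"center": [...], "radii":
    [...]}``; ``mesh``: params ``{"path": "volume.obj"}`` — any watertight
    mesh format trimesh can load.
    """

    kind: str
    params: dict
    _mesh: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("axis_aligned_box", "ellipsoid", "mesh"):
            raise ConfigError(f"unknown neuropil volume kind {self.kind!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment test; accepts (3,) or (n, 3) arrays."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "axis_aligned_box":
            lo = np.asarray(self.params["min"], dtype=float)
            hi = np.asarray(self.params["max"], dtype=float)
            out = np.all((pts >= lo) & (pts <= hi), axis=1)
        elif self.kind == "ellipsoid":
            c = np.asarray(self.params["center"], dtype=float)
            r = np.asarray(self.params["radii"], dtype=float)
            out = (((pts - c) / r) ** 2).sum(axis=1) <= 1.0
        else:  # mesh
            if self._mesh is None:
                import trimesh

                self._mesh = trimesh.load(self.params["path"], force="mesh")
            out = np.asarray(self._mesh.contains(pts), dtype=bool)
        if np.asarray(points).ndim == 1:
            return bool(out[0])
        return out

    def to_json(self) -> dict:
        return {"kind": self.kind, "params": self.params}

    @classmethod
    def from_json(cls, obj: dict) -> "NeuropilVolume":
        return cls(kind=obj["kind"], params=obj["params"])


def read_neuropil_volume(path: str | Path) -> NeuropilVolume:
    with open(path) as fh:
        return NeuropilVolume.from_json(json.load(fh))


def write_neuropil_volume(volume: NeuropilVolume, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(volume.to_json(), fh, indent=2)
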
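"""Ground-truth-labelled synthetic connectomes.

The generator emulates the statistical structure of a larval ventral nerve
cord hemisegment pair at synapse resolution, so every analysis stage can be
validated against known labels without any reconstruction data:

* bilateral hemisegments: the right side is the x-mirrored copy of the left
  with Gaussian coordinate jitter, giving exact homolog pairs;
* each neuroblast lineage contributes a dorsal and a ventral hemilineage
  whose synapse clouds occupy the +y and -y halves of the neuropil;
* somata sit in a cortex shell outside the neuropil, with the geodesic
  soma-to-neuropil path length (cortex neurite length) encoding birth
  order in up to four temporal groups calibrated against reference Hb+
  (early) and Cas+ (late) length distributions;
* each hemilineage-temporal (HL-T) cohort concentrates its signature
  synapse polarity (presynapses for dorsal, postsynapses for ventral
  cohorts) in a cohort-specific Gaussian cloud of spread ``cluster_sd``,
  with the opposite polarity spread diffusely over the hemilineage
  territory;
* sensory neurons place purely ventral presynapses and motor neurons purely
  dorsal postsynapses;
* connectivity follows proximity: each neuron's output degree is drawn at
  random and its targets are sampled without replacement with probability
  proportional to the pre/post overlap score of the generating clouds,
  multiplied by ``1 + hlt_bonus`` on designated HL-T cohort pairs.  With
  ``hlt_bonus = 0`` the ground truth *is* the degree-preserving proximity
  null of the analysis, which makes type-I-error calibration well-posed;
* presynaptic sites are polyadic, with partner counts of
  ``1 + Poisson(polyadic_mean - 1)``.

Everything is reproducible from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    Connector,
    NeuropilVolume,
    Skeleton,
    annotations_to_frame,
    NeuronAnnotation,
    read_annotation_table,
    read_connector_table,
    read_swc,
    write_annotation_table,
    write_connector_table,
    write_swc,
)
from .synapse_maps import SynapseSimilarityParams, overlap_matrix

logger = logging.getLogger(__name__)


def default_neuropil() -> NeuropilVolume:
    """The default neuropil: an axis-aligned box, 40 x 30 x 60 um (nm units)."""
    return NeuropilVolume(
        kind="axis_aligned_box",
        params={"min": [-20000.0, -15000.0, 0.0], "max": [20000.0, 15000.0, 60000.0]},
    )


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic connectome.

    Structural counts mirror an abdominal hemisegment: ``n_lineages``
    neuroblast lineages, each with a dorsal and a ventral hemilineage of
    up to four temporal groups, ``neurons_per_hlt`` neurons per HL-T
    cohort, plus sensory and motor populations.  All length scales in nm.

    ``base_connection_scale`` is the expected output degree per neuron;
    target identity is proximity-driven (see module docstring), and
    ``hlt_bonus`` multiplies the sampling weight of designated HL-T cohort
    pairs by ``1 + hlt_bonus``.
    """

    n_lineages: int = 7
    temporal_groups_per_hemilineage: int = 4
    neurons_per_hlt: int = 3
    neuropil: NeuropilVolume = field(default_factory=default_neuropil)
    cortex_shell_thickness: float = 40000.0
    radial_noise_sd: float = 1000.0
    cluster_sd: float = 1500.0
    presyn_per_neuron: float = 30.0
    postsyn_per_neuron: float = 30.0
    polyadic_mean: float = 2.0
    base_connection_scale: float = 10.0
    hlt_bonus: float = 4.0
    mirror_jitter_sd: float = 250.0
    seed: int = 0
    # reference populations anchoring the temporal bins
    hb_mean: float = 8000.0
    hb_sd: float = 1500.0
    cas_mean: float = 30000.0
    cas_sd: float = 4000.0
    n_reference_cells: int = 40
    # accessory populations and connectivity shape
    n_sensory_per_side: int = 10
    n_motor_per_side: int = 8
    designated_pair_fraction: float = 0.30
    contacts_per_edge_mean: float = 2.0
    diffuse_sd_factor: float = 5.0

    def __post_init__(self) -> None:
        if isinstance(self.neuropil, dict):
            self.neuropil = NeuropilVolume.from_json(self.neuropil)
        if min(self.n_lineages, self.neurons_per_hlt, self.temporal_groups_per_hemilineage) < 1:
            raise ConfigError("lineage/cohort counts must be positive")
        if self.temporal_groups_per_hemilineage > 4:
            raise ConfigError("at most four temporal groups are supported")
        if self.hlt_bonus < 0:
            raise ConfigError("hlt_bonus must be >= 0")
        if self.polyadic_mean < 1:
            raise ConfigError("polyadic_mean must be >= 1")
        if self.neuropil.kind != "axis_aligned_box":
            raise ConfigError("the generator requires an axis_aligned_box neuropil")
        lo = np.asarray(self.neuropil.params["min"], dtype=float)
        hi = np.asarray(self.neuropil.params["max"], dtype=float)
        if not (hi > lo).all():
            raise ConfigError("neuropil box must have positive extent")
        # dorsal and ventral anchor planes sit at +-0.55 of the half-height;
        # they must be separated by more than twice the cloud spread
        half_height = 0.5 * (hi[1] - lo[1])
        if 1.1 * half_height <= 2.0 * self.cluster_sd:
            raise ConfigError(
                "neuropil too small to separate dorsal and ventral synapse clouds "
                f"by > 2 x cluster_sd ({self.cluster_sd} nm)"
            )
        t1, t2, t3 = self.temporal_cutpoints()
        if not (t1 < t2 < t3):
            raise ConfigError("reference length distributions do not yield ordered bins")

    def temporal_cutpoints(self) -> tuple[float, float, float]:
        return (
            self.hb_mean + self.hb_sd,
            self.cas_mean - self.cas_sd,
            self.cas_mean,
        )

    def temporal_bin_edges(self) -> np.ndarray:
        t1, t2, t3 = self.temporal_cutpoints()
        outer = min(self.cortex_shell_thickness, t3 + (t3 - t2))
        return np.array([2000.0, t1, t2, t3, outer])

    def to_json(self) -> dict:
        obj = asdict(self)
        obj["neuropil"] = self.neuropil.to_json()
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "GeneratorConfig":
        obj = dict(obj)
        obj["neuropil"] = NeuropilVolume.from_json(obj["neuropil"])
        return cls(**obj)


def cohort_label(lineage: str, hemilineage: str, temporal_group: int) -> str:
    """Side-agnostic HL-T cohort label, e.g. ``NB3:dorsal:T2``."""
    return f"{lineage}:{hemilineage}:T{int(temporal_group)}"


@dataclass
class SyntheticConnectome:
    """A generated (or loaded) connectome bundle with ground-truth labels."""

    skeletons: dict[str, Skeleton]
    connectors: list[Connector]
    annotations: pd.DataFrame
    designated_pairs: list[tuple[str, str]]
    config: GeneratorConfig
    reference_lengths: dict[str, list[float]]
    true_cortex_length: dict[str, float]
    clouds: dict[str, dict[str, np.ndarray]] | None = field(default=None, repr=False)

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.annotations["neuron_id"])


@dataclass
class _NeuronSpec:
    neuron_id: str
    lineage: str
    hemilineage: str
    temporal_group: int | str
    hemisegment: str
    homolog_id: str
    cell_class: str
    cortex_length: float
    pre_center: np.ndarray | None
    pre_sd: float
    post_center: np.ndarray | None
    post_sd: float
    arbor_center: np.ndarray
    trunk_anchor: np.ndarray | None = None


def _box_bounds(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.asarray(config.neuropil.params["min"], dtype=float),
        np.asarray(config.neuropil.params["max"], dtype=float),
    )


def _draw_cortex_length(rng, config: GeneratorConfig, group: int) -> float:
    edges = config.temporal_bin_edges()
    lo, hi = edges[group - 1], edges[group]
    # margins keep each group's lengths clear of the bin boundaries, so that
    # boundary estimates refitted from finite reference samples still
    # separate the groups (reference-noise se is well below the margin)
    margin = min(2000.0, 0.45 * (hi - lo))
    center = 0.5 * (lo + hi)
    return float(np.clip(rng.normal(center, config.radial_noise_sd), lo + margin, hi - margin))


def _left_layout(config: GeneratorConfig, rng: np.random.Generator) -> list[_NeuronSpec]:
    """Place left-hemisegment neurons: clouds, cortex lengths, identities."""
    lo, hi = _box_bounds(config)
    width, height, depth = hi - lo
    xc, yc = 0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1])
    T = config.temporal_groups_per_hemilineage
    specs: list[_NeuronSpec] = []

    for li in range(config.n_lineages):
        lineage = f"NB{li + 1}"
        z_anchor = lo[2] + depth * (li + 0.5) / config.n_lineages
        x_anchor = xc - (0.35 if li % 2 == 0 else 0.175) * width
        for hemilineage, ysign in (("dorsal", +1.0), ("ventral", -1.0)):
            anchor = np.array([x_anchor, yc + ysign * 0.275 * height, z_anchor])
            # cohort-specific signature centers on a ring around the anchor
            ring = 2800.0
            centers = []
            for t in range(T):
                ang = 2.0 * np.pi * (t + 0.37) / T
                offset = np.array([ring * np.cos(ang), 0.0, ring * np.sin(ang)])
                centers.append(anchor + offset + rng.normal(0.0, 300.0, 3))
            for t in range(T):
                for k in range(config.neurons_per_hlt):
                    hid = f"{lineage}-{hemilineage[0]}-T{t + 1}-{k}"
                    group = t + 1
                    signature = centers[t]
                    diffuse_sd = config.diffuse_sd_factor * config.cluster_sd
                    if hemilineage == "dorsal":
                        pre_center, pre_sd = signature, config.cluster_sd
                        post_center, post_sd = anchor, diffuse_sd
                    else:
                        post_center, post_sd = signature, config.cluster_sd
                        pre_center, pre_sd = anchor, diffuse_sd
                    specs.append(
                        _NeuronSpec(
                            neuron_id=f"{hid}-L",
                            lineage=lineage,
                            hemilineage=hemilineage,
                            temporal_group=group,
                            hemisegment="left",
                            homolog_id=hid,
                            cell_class="interneuron",
                            cortex_length=_draw_cortex_length(rng, config, group),
                            pre_center=pre_center,
                            pre_sd=pre_sd,
                            post_center=post_center,
                            post_sd=post_sd,
                            arbor_center=signature,
                            trunk_anchor=anchor + rng.normal(0.0, 500.0, 3),
                        )
                    )

    for s in range(config.n_sensory_per_side):
        center = np.array(
            [
                xc - width * rng.uniform(0.1, 0.3),
                yc - height * rng.uniform(0.15, 0.38),
                lo[2] + depth * rng.uniform(0.15, 0.85),
            ]
        )
        hid = f"sens-{s:02d}"
        specs.append(
            _NeuronSpec(
                neuron_id=f"{hid}-L",
                lineage="sensory",
                hemilineage="unassigned",
                temporal_group="unassigned",
                hemisegment="left",
                homolog_id=hid,
                cell_class="sensory",
                cortex_length=float(rng.uniform(3000.0, 12000.0)),
                pre_center=center,
                pre_sd=2.0 * config.cluster_sd,
                post_center=None,
                post_sd=0.0,
                arbor_center=center,
            )
        )
    for m in range(config.n_motor_per_side):
        center = np.array(
            [
                xc - width * rng.uniform(0.1, 0.3),
                yc + height * rng.uniform(0.15, 0.38),
                lo[2] + depth * rng.uniform(0.15, 0.85),
            ]
        )
        hid = f"mot-{m:02d}"
        specs.append(
            _NeuronSpec(
                neuron_id=f"{hid}-L",
                lineage="motor",
                hemilineage="unassigned",
                temporal_group="unassigned",
                hemisegment="left",
                homolog_id=hid,
                cell_class="motor",
                cortex_length=float(rng.uniform(3000.0, 12000.0)),
                pre_center=None,
                pre_sd=0.0,
                post_center=center,
                post_sd=2.0 * config.cluster_sd,
                arbor_center=center,
            )
        )
    return specs


def _clip_into_box(points: np.ndarray, lo: np.ndarray, hi: np.ndarray, margin=200.0) -> np.ndarray:
    return np.clip(points, lo + margin, hi - margin)


def _draw_clouds(
    specs: list[_NeuronSpec], config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    lo, hi = _box_bounds(config)
    clouds: dict[str, dict[str, np.ndarray]] = {}
    for sp in specs:
        entry: dict[str, np.ndarray] = {}
        if sp.pre_center is not None:
            n = 1 + rng.poisson(max(config.presyn_per_neuron - 1.0, 0.0))
            entry["pre"] = _clip_into_box(
                sp.pre_center + rng.normal(0.0, sp.pre_sd, (n, 3)), lo, hi
            )
        else:
            entry["pre"] = np.empty((0, 3))
        if sp.post_center is not None:
            n = 1 + rng.poisson(max(config.postsyn_per_neuron - 1.0, 0.0))
            entry["post"] = _clip_into_box(
                sp.post_center + rng.normal(0.0, sp.post_sd, (n, 3)), lo, hi
            )
        else:
            entry["post"] = np.empty((0, 3))
        clouds[sp.neuron_id] = entry
    return clouds


def _build_skeleton(sp: _NeuronSpec, config: GeneratorConfig, rng: np.random.Generator) -> Skeleton:
    """Soma outside the neuropil, a 3-segment collinear cortex neurite of
    exactly the intended length to the entry node on the box face, then a
    small branched arbor at the cloud anchor."""
    lo, hi = _box_bounds(config)
    center = sp.arbor_center
    if sp.cell_class == "sensory":  # enters through the ventral face
        entry = np.array([center[0], lo[1], center[2]])
        outward = np.array([0.0, -1.0, 0.0])
    elif sp.cell_class == "motor":  # exits through the dorsal face
        entry = np.array([center[0], hi[1], center[2]])
        outward = np.array([0.0, 1.0, 0.0])
    else:  # interneurons enter laterally
        entry = np.array(
            [lo[0], np.clip(center[1], lo[1] + 1000, hi[1] - 1000), center[2]]
        )
        outward = np.array([-1.0, 0.0, 0.0])
    tilt = rng.normal(0.0, 0.05, 3)
    tilt -= tilt @ outward * outward
    u = outward + tilt
    u = u / np.linalg.norm(u)
    soma = entry + sp.cortex_length * u
    n_tips = 3 if sp.cell_class == "interneuron" else 2
    tips = _clip_into_box(center + rng.normal(0.0, 2.0 * config.cluster_sd, (n_tips, 3)), lo, hi)
    coords = [soma, entry + (2.0 / 3.0) * sp.cortex_length * u, entry + (1.0 / 3.0) * sp.cortex_length * u, entry]
    parents = [-1, 1, 2, 3]
    if sp.trunk_anchor is not None:
        # hemilineage neurite bundle: all cohorts of a hemilineage share the
        # trunk from the entry point to the hemilineage territory
        coords.append(_clip_into_box(sp.trunk_anchor, lo, hi))
        parents.append(4)
    coords.append(center)
    parents.append(len(coords) - 1)
    center_node = len(coords)
    for tip in tips:
        coords.append(tip)
        parents.append(center_node)  # tips branch from the arbor center node
    node_ids = np.arange(1, len(coords) + 1)
    radii = np.full(len(coords), 150.0)
    radii[0] = 2000.0
    return Skeleton(
        neuron_id=sp.neuron_id,
        node_ids=node_ids,
        parent_ids=np.array(parents),
        coords=np.array(coords),
        radii=radii,
    )


def _choose_designated_pairs(
    specs: list[_NeuronSpec],
    overlap: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Designate mid-overlap HL-T cohort pairs to receive the bonus.

    Eligibility is based on the mean *overlap share* (each neuron's
    overlap row normalized to 1, the quantity that sets proximity-driven
    connection rates): pairs with mean share in [0.002, 0.05] are
    physically plausible partners (the bonus acts through
    overlap-proportional sampling, so zero-overlap pairs cannot gain
    edges) yet not so close that proximity alone already connects them —
    extra connectivity there models partner choice beyond what Peter's
    rule predicts.
    """
    cohort_of = {
        sp.neuron_id: cohort_label(sp.lineage, sp.hemilineage, sp.temporal_group)
        for sp in specs
        if sp.cell_class == "interneuron"
    }
    members: dict[str, list[str]] = {}
    for nid, c in cohort_of.items():
        members.setdefault(c, []).append(nid)
    labels = sorted(members)
    O = overlap.to_numpy().copy()
    if overlap.index.equals(overlap.columns):
        np.fill_diagonal(O, 0.0)
    shares = O / np.maximum(O.sum(axis=1, keepdims=True), 1e-300)
    share_df = pd.DataFrame(shares, index=overlap.index, columns=overlap.columns)
    means = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            block = share_df.loc[members[a], members[b]].to_numpy()
            means[(a, b)] = float(block.mean())
    eligible = sorted([pair for pair, v in means.items() if 0.002 <= v <= 0.05])
    if not eligible:
        return []
    n_pairs = len(labels) * (len(labels) - 1)
    n_designated = min(len(eligible), max(1, round(config.designated_pair_fraction * n_pairs)))
    chosen = rng.choice(len(eligible), size=n_designated, replace=False)
    return [eligible[i] for i in sorted(chosen)]


def _sample_connectivity(
    specs: list[_NeuronSpec],
    overlap: pd.DataFrame,
    designated: list[tuple[str, str]],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, int]]]:
    """Draw each neuron's targets and contact counts (left side).

    Proximity baseline: each neuron draws an output degree
    ``d ~ Poisson(base_connection_scale)`` and samples ``d`` distinct
    targets without replacement with probability proportional to the
    pre/post overlap score — exactly the generative law of the
    degree-preserving proximity null, so at ``hlt_bonus = 0`` observed and
    shuffled connectivity are exchangeable by construction.  On designated
    cohort pairs the bonus then *adds* edges: (i, j) gains an extra edge
    with probability ``min(0.5, hlt_bonus * base_connection_scale *
    overlap(i, j) / sum_k overlap(i, k))`` (the cap keeps extra edges per
    designated pair sparse rather than exhaustive), so the expected connection rate
    is proportional to ``overlap * (1 + hlt_bonus)`` up to the cap.  Each
    realized edge carries ``1 + Poisson(contacts_per_edge_mean - 1)``
    synaptic contacts.
    """
    cohort_of = {
        sp.neuron_id: cohort_label(sp.lineage, sp.hemilineage, sp.temporal_group)
        for sp in specs
        if sp.cell_class == "interneuron"
    }
    designated_set = set(designated)
    post_ids = list(overlap.columns)
    edges: dict[str, list[tuple[str, int]]] = {}
    for sp in specs:
        row = overlap.loc[sp.neuron_id].to_numpy().copy() if sp.neuron_id in overlap.index else None
        if row is None:
            continue
        if sp.neuron_id in overlap.columns:
            row[post_ids.index(sp.neuron_id)] = 0.0
        mass = row.sum()
        if mass <= 0:
            continue
        admissible = int(np.count_nonzero(row > 0))
        d = int(min(rng.poisson(config.base_connection_scale), admissible))
        targets = set()
        if d > 0:
            targets |= set(
                rng.choice(len(post_ids), size=d, replace=False, p=row / mass).tolist()
            )
        ca = cohort_of.get(sp.neuron_id)
        if ca is not None and config.hlt_bonus > 0:
            p_extra = np.minimum(
                0.5, config.hlt_bonus * config.base_connection_scale * row / mass
            )
            for j, nid in enumerate(post_ids):
                cb = cohort_of.get(nid)
                if (
                    cb is not None
                    and (ca, cb) in designated_set
                    and rng.random() < p_extra[j]
                ):
                    targets.add(j)
        if not targets:
            continue
        edges[sp.neuron_id] = [
            (post_ids[j], 1 + int(rng.poisson(config.contacts_per_edge_mean - 1.0)))
            for j in sorted(targets)
        ]
    return edges


def _build_connectors(
    edges: dict[str, list[tuple[str, int]]],
    specs_by_id: dict[str, _NeuronSpec],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[Connector]:
    lo, hi = _box_bounds(config)
    connectors: list[Connector] = []
    serial = 0
    for pre_id in sorted(edges):
        sp = specs_by_id[pre_id]
        slots: list[str] = []
        for target, contacts in edges[pre_id]:
            slots.extend([target] * contacts)
        perm = rng.permutation(len(slots))
        slots = [slots[i] for i in perm]
        pos = 0
        while pos < len(slots):
            m = 1 + int(rng.poisson(config.polyadic_mean - 1.0))
            chunk = slots[pos : pos + m]
            pos += m
            pre_loc = _clip_into_box(
                sp.pre_center + rng.normal(0.0, sp.pre_sd, 3), lo, hi
            )
            partners = []
            for target in chunk:
                tsp = specs_by_id[target]
                partners.append(
                    (
                        target,
                        _clip_into_box(
                            tsp.post_center + rng.normal(0.0, tsp.post_sd, 3), lo, hi
                        ),
                    )
                )
            serial += 1
            connectors.append(
                Connector(
                    connector_id=f"cn{serial:06d}-L",
                    pre_neuron=pre_id,
                    pre_location=pre_loc,
                    post_partners=partners,
                )
            )
    return connectors


def _mirror_point(p: np.ndarray, x_mid: float, jitter_sd: float, rng) -> np.ndarray:
    q = np.asarray(p, dtype=float).copy()
    q[0] = 2.0 * x_mid - q[0]
    return q + rng.normal(0.0, jitter_sd, q.shape)


def generate_connectome(config: GeneratorConfig) -> SyntheticConnectome:
    """Generate a labelled bilateral connectome from the study conditions.

    Fully reproducible from ``config.seed``: identical configs produce
    identical connectomes (and, through :func:`write_fixture`,
    byte-identical files).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = _box_bounds(config)
    x_mid = 0.5 * (lo[0] + hi[0])

    specs = _left_layout(config, rng)
    specs_by_id = {sp.neuron_id: sp for sp in specs}
    clouds = _draw_clouds(specs, config, rng)

    pre_clouds = {nid: c["pre"] for nid, c in clouds.items() if len(c["pre"])}
    post_clouds = {nid: c["post"] for nid, c in clouds.items() if len(c["post"])}
    params = SynapseSimilarityParams()
    overlap = overlap_matrix(pre_clouds, post_clouds, params)

    designated = _choose_designated_pairs(specs, overlap, config, rng)
    edges = _sample_connectivity(specs, overlap, designated, config, rng)
    left_connectors = _build_connectors(edges, specs_by_id, config, rng)

    skeletons: dict[str, Skeleton] = {}
    for sp in specs:
        skeletons[sp.neuron_id] = _build_skeleton(sp, config, rng)

    # mirror the left hemisegment onto the right
    annotations: list[NeuronAnnotation] = []
    true_lengths: dict[str, float] = {}
    all_connectors = list(left_connectors)
    all_clouds = {nid: c for nid, c in clouds.items()}
    jsd = config.mirror_jitter_sd
    for sp in specs:
        rid = f"{sp.homolog_id}-R"
        left_sk = skeletons[sp.neuron_id]
        was_inside = np.asarray(config.neuropil.contains(left_sk.coords))
        mirrored = left_sk.coords.copy()
        mirrored[:, 0] = 2.0 * x_mid - mirrored[:, 0]
        mirrored = mirrored + rng.normal(0.0, jsd, mirrored.shape)
        # jitter must not flip a node across the neuropil boundary, or the
        # right homolog's entry point (and cortex length) would shift
        mirrored[was_inside] = np.clip(mirrored[was_inside], lo, hi)
        now_inside = np.asarray(config.neuropil.contains(mirrored))
        for k in np.flatnonzero(~was_inside & now_inside):
            ax = int(np.argmin(np.minimum(mirrored[k] - lo, hi - mirrored[k])))
            if mirrored[k, ax] - lo[ax] < hi[ax] - mirrored[k, ax]:
                mirrored[k, ax] = lo[ax] - 1.0
            else:
                mirrored[k, ax] = hi[ax] + 1.0
        skeletons[rid] = Skeleton(
            neuron_id=rid,
            node_ids=left_sk.node_ids.copy(),
            parent_ids=left_sk.parent_ids.copy(),
            coords=mirrored,
            radii=left_sk.radii.copy(),
        )
        all_clouds[rid] = {
            pol: np.array(
                [_mirror_point(p, x_mid, jsd, rng) for p in all_clouds[sp.neuron_id][pol]]
            ).reshape(-1, 3)
            for pol in ("pre", "post")
        }
        for seg, nid in (("left", sp.neuron_id), ("right", rid)):
            annotations.append(
                NeuronAnnotation(
                    neuron_id=nid,
                    lineage=sp.lineage,
                    hemilineage=sp.hemilineage,
                    temporal_group=sp.temporal_group,
                    hemisegment=seg,
                    homolog_id=sp.homolog_id,
                    cell_class=sp.cell_class,
                )
            )
            true_lengths[nid] = sp.cortex_length
    for c in left_connectors:
        rid_pre = f"{specs_by_id[c.pre_neuron].homolog_id}-R"
        all_connectors.append(
            Connector(
                connector_id=c.connector_id[:-2] + "-R",
                pre_neuron=rid_pre,
                pre_location=_mirror_point(c.pre_location, x_mid, jsd, rng),
                post_partners=[
                    (
                        f"{specs_by_id[nid].homolog_id}-R",
                        _mirror_point(loc, x_mid, jsd, rng),
                    )
                    for nid, loc in c.post_partners
                ],
            )
        )

    reference_lengths = {
        "hb": rng.normal(config.hb_mean, config.hb_sd, config.n_reference_cells).tolist(),
        "cas": rng.normal(config.cas_mean, config.cas_sd, config.n_reference_cells).tolist(),
    }
    return SyntheticConnectome(
        skeletons=skeletons,
        connectors=all_connectors,
        annotations=annotations_to_frame(annotations),
        designated_pairs=designated,
        config=config,
        reference_lengths=reference_lengths,
        true_cortex_length=true_lengths,
        clouds=all_clouds,
    )


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------


def write_fixture(
    connectome: SyntheticConnectome, directory: str | Path, overwrite: bool = False
) -> None:
    """Write a connectome as a plain-text fixture.

    Layout: ``swc/<neuron_id>.swc`` per neuron, ``connectors.csv``,
    ``annotations.csv`` and ``truth.json`` (labels, designated cohort
    pairs, reference lengths and the full generator config).  Refuses to
    clobber an existing fixture unless ``overwrite`` is set.
    """
    directory = Path(directory)
    if (directory / "truth.json").exists() and not overwrite:
        raise FileExistsError(f"fixture already exists at {directory}; pass overwrite=True")
    (directory / "swc").mkdir(parents=True, exist_ok=True)
    for nid, sk in sorted(connectome.skeletons.items()):
        write_swc(sk, directory / "swc" / f"{nid}.swc")
    write_connector_table(connectome.connectors, directory / "connectors.csv")
    write_annotation_table(connectome.annotations, directory / "annotations.csv")
    labels = {
        row["neuron_id"]: {
            "lineage": row["lineage"],
            "hemilineage": row["hemilineage"],
            "temporal_group": row["temporal_group"],
            "hemisegment": row["hemisegment"],
            "homolog_id": row["homolog_id"],
            "cell_class": row["cell_class"],
        }
        for _, row in connectome.annotations.iterrows()
    }
    truth = {
        "labels": labels,
        "designated_pairs": [list(p) for p in connectome.designated_pairs],
        "config": connectome.config.to_json(),
        "reference_lengths": connectome.reference_lengths,
        "true_cortex_length": connectome.true_cortex_length,
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def load_fixture(directory: str | Path) -> SyntheticConnectome:
    """Load a fixture written by :func:`write_fixture` (clouds are not stored)."""
    directory = Path(directory)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    skeletons = {
        p.stem: read_swc(p) for p in sorted((directory / "swc").glob("*.swc"))
    }
    connectors = read_connector_table(directory / "connectors.csv")
    annotations = read_annotation_table(directory / "annotations.csv")
    return SyntheticConnectome(
        skeletons=skeletons,
        connectors=connectors,
        annotations=annotations,
        designated_pairs=[tuple(p) for p in truth["designated_pairs"]],
        config=GeneratorConfig.from_json(truth["config"]),
        reference_lengths=truth["reference_lengths"],
        true_cortex_length=truth["true_cortex_length"],
        clouds=None,
    )
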
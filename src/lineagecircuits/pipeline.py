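"""Config-driven orchestration of the full analysis.

Runs the stages in their natural order — morphometrics (cortex lengths,
temporal groups, hemilineage clustering), synapse maps (similarity
matrices, density maps), connectivity statistics (binarization, cosine
similarity, cohort comparisons) and Monte-Carlo null models — on either a
synthetic connectome generated in-process or a fixture directory on disk,
and emits a machine-readable report plus CSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import connectivity as conn_mod
from . import morphometrics as morpho
from . import null_models
from . import synapse_maps
from .core import ConfigError, binarize, build_connectivity
from .synthetic import (
    GeneratorConfig,
    SyntheticConnectome,
    generate_connectome,
    load_fixture,
    write_fixture,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Resolved settings for one analysis run.

    Exactly one of ``generator`` (synthetic mode) or ``fixture_dir`` must be
    set.  Thresholds default to the printed analysis conventions: a
    2-synapse binarization for null models, a strict >3-synapse rule for
    premotor/postsensory classification, 60% mass for the outermost density
    contour.
    """

    generator: GeneratorConfig | None = None
    fixture_dir: str | None = None
    out_dir: str | None = None
    sigma: float = 2000.0
    omega: float = 2000.0
    binarize_threshold: int = 2
    premotor_threshold: int = 3
    overlap_threshold: float = 0.0
    kde_bandwidth: float | str = "scott"
    contour_fraction: float = 0.6
    ap_window: tuple[float, float] | None = None
    null_mode: str = "overlap"
    n_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig.from_json(self.generator)
        if (self.generator is None) == (self.fixture_dir is None):
            raise ConfigError("set exactly one of generator / fixture_dir")
        if self.null_mode not in ("overlap", "input_degree"):
            raise ConfigError("null_mode must be 'overlap' or 'input_degree'")
        if self.binarize_threshold < 1:
            raise ConfigError("binarize_threshold must be >= 1")

    def to_json(self) -> dict:
        obj = asdict(self)
        if self.generator is not None:
            obj["generator"] = self.generator.to_json()
        if self.ap_window is not None:
            obj["ap_window"] = list(self.ap_window)
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        if obj.get("generator") is not None:
            obj["generator"] = GeneratorConfig.from_json(obj["generator"])
        if obj.get("ap_window") is not None:
            obj["ap_window"] = tuple(obj["ap_window"])
        return cls(**obj)


def _round12(obj):
    """Round all floats to 12 significant digits for byte-stable reports."""
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return x if (np.isnan(x) or np.isinf(x)) else float(f"{x:.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _load(config: PipelineConfig) -> SyntheticConnectome:
    if config.generator is not None:
        return generate_connectome(config.generator)
    return load_fixture(config.fixture_dir)


def morphometrics_stage(connectome: SyntheticConnectome, config: PipelineConfig) -> dict:
    """Cortex lengths, temporal groups and per-lineage hemilineage clusters."""
    volume = connectome.config.neuropil
    ann = connectome.annotations
    lengths = {
        nid: morpho.cortex_neurite_length(sk, volume)
        for nid, sk in connectome.skeletons.items()
    }
    bins = morpho.fit_temporal_bins(
        connectome.reference_lengths["hb"], connectome.reference_lengths["cas"]
    )

    rows = []
    for hid, grp in ann.groupby("homolog_id"):
        sides = grp.set_index("hemisegment")["neuron_id"]
        left = lengths.get(sides.get("left"))
        right = lengths.get(sides.get("right"))
        mean = morpho.bilateral_mean_length(left, right)
        rows.append(
            {
                "homolog_id": hid,
                "left": left,
                "right": right,
                "mean": mean,
                "group": morpho.assign_temporal_group(mean, bins) if mean is not None else None,
            }
        )
    lengths_df = pd.DataFrame(rows)

    inter = ann[ann["cell_class"] == "interneuron"]
    pred = {n: morpho.assign_temporal_group(lengths[n], bins) for n in inter["neuron_id"]}
    truth = inter["temporal_group"]
    accuracy = float(np.mean([pred[n] == truth[n] for n in inter["neuron_id"]]))

    cluster_rows, true_labels, pred_labels = [], [], []
    offset = 0
    for lineage, grp in inter[inter["hemisegment"] == "left"].groupby("lineage"):
        ids = list(grp["neuron_id"])
        dps = {
            n: morpho.to_dotprops(morpho.prune_by_strahler(connectome.skeletons[n], 2))
            for n in ids
        }
        S = np.array(
            [[morpho.morph_similarity(dps[a], dps[b]) for b in ids] for a in ids]
        )
        labels = morpho.cluster_hemilineages(S)
        for n, lab in zip(ids, labels):
            cluster_rows.append({"neuron_id": n, "lineage": lineage, "cluster": int(lab)})
        true_labels += [f"{lineage}:{grp.loc[n, 'hemilineage']}" for n in ids]
        pred_labels += [int(lab) + offset for lab in labels]
        offset += int(labels.max()) + 1
    clusters_df = pd.DataFrame(cluster_rows)
    ari = float(adjusted_rand_score(true_labels, pred_labels)) if true_labels else float("nan")

    return {
        "lengths": lengths_df,
        "clusters": clusters_df,
        "per_neuron_length": lengths,
        "summary": {
            "temporal_bins": {"t1": bins.t1, "t2": bins.t2, "t3": bins.t3},
            "temporal_assignment_accuracy": accuracy,
            "hemilineage_ari": ari,
            "n_neurons": int(len(ann)),
        },
    }


def synapse_stage(connectome: SyntheticConnectome, config: PipelineConfig) -> dict:
    """Similarity matrices and density maps from realized synapse positions."""
    params = synapse_maps.SynapseSimilarityParams(sigma=config.sigma, omega=config.omega)
    syns = synapse_maps.synapses_from_connectors(connectome.connectors)
    ann = connectome.annotations
    sim_pre = synapse_maps.similarity_matrix(syns, ann, mode="pre_pre", params=params)
    sim_post = synapse_maps.similarity_matrix(syns, ann, mode="post_post", params=params)

    maps = {}
    inter = ann[(ann["cell_class"] == "interneuron") & (ann["hemisegment"] == "left")]
    for hl in ("dorsal", "ventral"):
        ids = inter[inter["hemilineage"] == hl]["neuron_id"]
        pol = "pre" if hl == "dorsal" else "post"
        pts = np.vstack([syns[n][pol] for n in ids if n in syns and len(syns[n][pol])])
        if len(pts) >= 2:
            maps[f"{hl}_{pol}"] = synapse_maps.density_map(
                pts,
                bandwidth=config.kde_bandwidth,
                contour_fraction=config.contour_fraction,
                ap_window=config.ap_window,
            )
    return {"pre_pre": sim_pre, "post_post": sim_post, "density_maps": maps, "synapses": syns}


def connectivity_stage(
    connectome: SyntheticConnectome, synmaps: dict, config: PipelineConfig
) -> dict:
    """Connectivity matrices, cosine similarity and cohort comparisons."""
    ann = connectome.annotations
    ids = list(ann["neuron_id"])
    matrix = build_connectivity(connectome.connectors, ids)
    binary = binarize(matrix, config.binarize_threshold)
    cos_out = conn_mod.connectivity_similarity(binary, axis="outputs")
    dist = conn_mod.network_distance(binary)

    motor = list(ann[ann["cell_class"] == "motor"]["neuron_id"])
    sensory = list(ann[ann["cell_class"] == "sensory"]["neuron_id"])
    flags = conn_mod.classify_premotor_postsensory(
        matrix, motor, sensory, threshold=config.premotor_threshold
    )

    groupings = conn_mod.build_standard_groupings(ann, rng=config.seed)
    comparison = conn_mod.cohort_comparison(synmaps["pre_pre"], groupings, annotations=ann)

    finite = dist.to_numpy()[np.isfinite(dist.to_numpy())]
    return {
        "matrix": matrix,
        "binary": binary,
        "cosine_outputs": cos_out,
        "network_distance": dist,
        "flags": flags,
        "comparison": comparison,
        "summary": {
            "n_edges": int(np.count_nonzero(binary.matrix)),
            "binarize_threshold": config.binarize_threshold,
            "n_premotor": int(flags["premotor"].sum()),
            "n_postsensory": int(flags["postsensory"].sum()),
            "median_finite_network_distance": float(np.median(finite)) if finite.size else None,
        },
    }


def null_stage(connectome: SyntheticConnectome, config: PipelineConfig) -> dict:
    """Degree-preserving null of the HL-T cohort connection frequency.

    The analysis is restricted to left-hemisegment interneurons (cohorts
    are hemisegment-local) and conditions the connection-probability model
    on the realized pre/post synapse positions.
    """
    ann = connectome.annotations
    left = ann[(ann["hemisegment"] == "left") & (ann["cell_class"] == "interneuron")]
    ids = list(left["neuron_id"])
    matrix = build_connectivity(connectome.connectors, ids)
    binary = binarize(matrix, config.binarize_threshold)
    cohorts = conn_mod.hlt_cohorts(ann, hemisegment="left")

    if config.null_mode == "overlap":
        syns = synapse_maps.synapses_from_connectors(connectome.connectors)
        params = synapse_maps.SynapseSimilarityParams(sigma=config.sigma, omega=config.omega)
        empty = np.empty((0, 3))
        pre = {n: syns.get(n, {}).get("pre", empty) for n in ids}
        post = {n: syns.get(n, {}).get("post", empty) for n in ids}
        overlap = synapse_maps.overlap_matrix(pre, post, params).to_numpy()
        model = null_models.connection_probabilities(
            "overlap", overlap, overlap_threshold=config.overlap_threshold
        )
    else:
        model = null_models.connection_probabilities("input_degree", binary)

    result = null_models.null_distribution(
        binary, model, cohorts, n_iter=config.n_iter, seed=config.seed
    )
    return {"result": result, "summary": result.manifest()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return (and optionally write) the report.

    Deterministic for a fixed config and seed.  Stage failures raise
    :class:`PipelineError` naming the stage; artifacts of completed stages
    are preserved in ``out_dir``.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "resolved_config.json", "w") as fh:
            json.dump(_round12(config.to_json()), fh, indent=1, sort_keys=True)

    report: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                    "config": config.to_json()}

    stage = "load"
    try:
        connectome = _load(config)
        report["n_neurons"] = len(connectome.annotations)
        report["n_connectors"] = len(connectome.connectors)

        stage = "morphometrics"
        m = morphometrics_stage(connectome, config)
        report["morphometrics"] = m["summary"]
        if out is not None:
            m["lengths"].to_csv(out / "lengths.csv", index=False)
            m["clusters"].to_csv(out / "hemilineage_labels.csv", index=False)

        stage = "synapse_maps"
        s = synapse_stage(connectome, config)
        report["synapse_maps"] = {
            "sigma": config.sigma,
            "omega": config.omega,
            "n_scored_pre": int(len(s["pre_pre"])),
            "n_scored_post": int(len(s["post_post"])),
            "density_maps": {
                name: {
                    "contour_level": dm.contour_level,
                    "enclosed_mass": dm.enclosed_mass(),
                }
                for name, dm in s["density_maps"].items()
            },
        }
        if out is not None:
            s["pre_pre"].to_csv(out / "similarity_pre_pre.csv")
            s["post_post"].to_csv(out / "similarity_post_post.csv")
            for name, dm in s["density_maps"].items():
                synapse_maps.write_density_map(dm, out / f"density_{name}.txt")

        stage = "connectivity"
        c = connectivity_stage(connectome, s, config)
        report["connectivity"] = c["summary"]
        report["cohort_comparison"] = {
            "summary": c["comparison"].summary.to_dict(orient="records"),
            "tests": c["comparison"].tests.to_dict(orient="records"),
        }
        if out is not None:
            c["matrix"].to_dataframe().to_csv(out / "connectivity_counts.csv")
            c["comparison"].summary.to_csv(out / "cohort_stats.csv", index=False)
            c["comparison"].tests.to_csv(out / "cohort_tests.csv", index=False)

        stage = "null_models"
        n = null_stage(connectome, config)
        report["null_model"] = n["summary"]
        if out is not None:
            pd.DataFrame({"sample": n["result"].samples}).to_csv(
                out / "null_samples.csv", index=False
            )
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        raise PipelineError(stage, exc) from exc

    report = _round12(report)
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "morphometrics_stage",
    "synapse_stage",
    "connectivity_stage",
    "null_stage",
]
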
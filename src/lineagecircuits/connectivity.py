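"""Connectivity-side statistics.

Premotor/postsensory classification, group input/output fractions, cosine
similarity of binarized connection vectors, synaptic network distance, and
comparisons of pairwise scores across developmental groupings (unrelated,
temporal-only, hemilineage-only, hemilineage-temporal) with the rank-sum
and Kolmogorov-Smirnov tests used for non-normal score distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy import stats

from .core import BinaryConnectivity, ConnectivityMatrix

GROUPING_KINDS = (
    "unrelated_same_hemisegment",
    "temporal_only",
    "hemilineage_only",
    "hemilineage_temporal",
)


def classify_premotor_postsensory(
    matrix: ConnectivityMatrix,
    motor_ids,
    sensory_ids,
    threshold: int = 3,
    per_partner: bool = True,
) -> pd.DataFrame:
    """Flag neurons as premotor and/or postsensory.

    A neuron is premotor if it places strictly more than ``threshold``
    synapses onto a single motor neuron (``per_partner=True``, the default
    reading of "onto a motor neuron"), or onto all motor neurons combined
    (``per_partner=False``).  Postsensory is the symmetric condition on
    inputs from sensory neurons.
    """
    motor = [m for m in map(str, motor_ids) if m in matrix.neuron_ids]
    sensory = [s for s in map(str, sensory_ids) if s in matrix.neuron_ids]
    if set(motor) & set(sensory):
        raise ValueError("motor and sensory id sets must be disjoint")
    df = matrix.to_dataframe()
    onto_motor = df[motor] if motor else pd.DataFrame(index=df.index)
    from_sensory = df.loc[sensory] if sensory else pd.DataFrame(columns=df.columns)
    if per_partner:
        pre = onto_motor.max(axis=1) if motor else pd.Series(0, index=df.index)
        post = from_sensory.max(axis=0) if sensory else pd.Series(0, index=df.columns)
    else:
        pre = onto_motor.sum(axis=1) if motor else pd.Series(0, index=df.index)
        post = from_sensory.sum(axis=0) if sensory else pd.Series(0, index=df.columns)
    out = pd.DataFrame(
        {
            "premotor": (pre > threshold).astype(bool),
            "postsensory": (post > threshold).astype(bool),
        },
        index=df.index,
    )
    out.index.name = "neuron_id"
    return out.drop(index=motor + sensory, errors="ignore")


def group_io_fractions(
    matrix: ConnectivityMatrix,
    source_ids,
    target_groups: dict[str, list],
    direction: str = "outputs",
) -> pd.DataFrame:
    """Fraction of a source set's synaptic outputs (or inputs) per target group.

    For ``direction='outputs'`` the denominator is the total number of
    synaptic outputs of the source set onto any neuron in the matrix, so
    fractions over the listed groups sum to <= 1 (the remainder lands on
    unlisted neurons).  ``direction='inputs'`` is the symmetric version.
    """
    if direction not in ("outputs", "inputs"):
        raise ValueError("direction must be 'outputs' or 'inputs'")
    df = matrix.to_dataframe()
    src = [s for s in map(str, source_ids) if s in df.index]
    block = df.loc[src] if direction == "outputs" else df[src].T
    total = float(block.to_numpy().sum())
    rows = []
    for label, members in target_groups.items():
        members = [m for m in map(str, members) if m in df.columns]
        n_syn = float(block[members].to_numpy().sum()) if members else 0.0
        rows.append(
            {
                "group": label,
                "n_synapses": int(n_syn),
                "fraction": n_syn / total if total > 0 else np.nan,
            }
        )
    if total == 0:
        warnings.warn("source set has zero total synapses; fractions undefined", stacklevel=2)
    out = pd.DataFrame(rows)
    out.attrs["direction"] = direction
    out.attrs["total_synapses"] = int(total)
    return out


def connectivity_similarity(binary: BinaryConnectivity, axis: str = "outputs") -> pd.DataFrame:
    """Cosine similarity of binarized connection vectors.

    ``axis='outputs'`` compares row vectors (shared targets), ``'inputs'``
    compares column vectors (shared sources).  Pairs involving an all-zero
    vector score 0 and are flagged in ``attrs['zero_vectors']``.
    """
    if axis not in ("outputs", "inputs"):
        raise ValueError("axis must be 'outputs' or 'inputs'")
    M = np.asarray(binary.matrix, dtype=float)
    V = M if axis == "outputs" else M.T
    norms = np.linalg.norm(V, axis=1)
    sim = V @ V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = sim / np.outer(norms, norms)
    sim[~np.isfinite(sim)] = 0.0
    out = pd.DataFrame(sim, index=binary.neuron_ids, columns=binary.neuron_ids)
    out.attrs["axis"] = axis
    out.attrs["threshold"] = binary.threshold
    out.attrs["zero_vectors"] = [binary.neuron_ids[i] for i in np.flatnonzero(norms == 0)]
    return out


def network_distance(binary: BinaryConnectivity) -> pd.DataFrame:
    """Shortest path length, in synapses, between all neuron pairs.

    Paths are direction-blind: two neurons sharing a common input or a
    common output are two synapses apart, which forces the undirected view
    of the binarized graph.  Unreachable pairs are ``inf``.
    """
    graph = csr_matrix(np.asarray(binary.matrix, dtype=np.int8))
    dist = shortest_path(graph, method="D", directed=False, unweighted=True)
    return pd.DataFrame(dist, index=binary.neuron_ids, columns=binary.neuron_ids)


# ---------------------------------------------------------------------------
# Cohort groupings and statistical comparison
# ---------------------------------------------------------------------------


@dataclass
class CohortGrouping:
    """A named partition of neurons into cohorts of shared developmental origin.

    ``kind`` selects which within-cohort pairs are eligible: for
    ``hemilineage_only`` pairs sharing a temporal group are excluded (those
    belong to the finer hemilineage-temporal grouping), and for
    ``temporal_only`` pairs from the same hemilineage are excluded.
    """

    kind: str
    members: dict[str, list]

    def __post_init__(self) -> None:
        if self.kind not in GROUPING_KINDS:
            raise ValueError(f"unknown grouping kind {self.kind!r}")
        seen: set = set()
        for label, ids in self.members.items():
            ids = list(map(str, ids))
            if seen & set(ids):
                raise ValueError(f"cohort {label}: cohorts must be disjoint within a grouping")
            seen |= set(ids)
            self.members[label] = ids


def hlt_cohorts(annotations: pd.DataFrame, hemisegment: str | None = None) -> dict[str, list]:
    """Hemilineage-temporal cohort membership from an annotation table.

    Only interneurons with assigned hemilineage and temporal group are
    grouped; cohort labels read ``lineage:hemilineage:T<t>:<hemisegment>``.
    """
    ann = annotations
    if hemisegment is not None:
        ann = ann[ann["hemisegment"] == hemisegment]
    ann = ann[
        (ann["cell_class"] == "interneuron")
        & (ann["hemilineage"].isin(["dorsal", "ventral"]))
        & (ann["temporal_group"] != "unassigned")
    ]
    out: dict[str, list] = {}
    for (lin, hl, t, seg), grp in ann.groupby(
        ["lineage", "hemilineage", "temporal_group", "hemisegment"]
    ):
        out[f"{lin}:{hl}:T{int(t)}:{seg}"] = list(grp["neuron_id"])
    return out


def build_standard_groupings(
    annotations: pd.DataFrame,
    rng: np.random.Generator | int | None = 0,
    random_cohort_size: int = 3,
) -> list[CohortGrouping]:
    """The four standard groupings used for cohort comparisons.

    The unrelated baseline draws random pseudo-cohorts of
    ``random_cohort_size`` neurons from within each hemisegment, matching
    the convention that baseline pairs share a hemisegment but nothing
    else by design.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ann = annotations[
        (annotations["cell_class"] == "interneuron")
        & (annotations["hemilineage"].isin(["dorsal", "ventral"]))
        & (annotations["temporal_group"] != "unassigned")
    ]
    groupings = []

    random_members: dict[str, list] = {}
    for seg, grp in ann.groupby("hemisegment"):
        ids = list(grp["neuron_id"])
        rng.shuffle(ids)
        for c, start in enumerate(range(0, len(ids) - random_cohort_size + 1, random_cohort_size)):
            random_members[f"random:{seg}:{c}"] = ids[start : start + random_cohort_size]
    groupings.append(CohortGrouping("unrelated_same_hemisegment", random_members))

    temporal_members = {
        f"T{int(t)}:{seg}": list(grp["neuron_id"])
        for (t, seg), grp in ann.groupby(["temporal_group", "hemisegment"])
    }
    groupings.append(CohortGrouping("temporal_only", temporal_members))

    hl_members = {
        f"{lin}:{hl}:{seg}": list(grp["neuron_id"])
        for (lin, hl, seg), grp in ann.groupby(["lineage", "hemilineage", "hemisegment"])
    }
    groupings.append(CohortGrouping("hemilineage_only", hl_members))

    groupings.append(CohortGrouping("hemilineage_temporal", hlt_cohorts(annotations)))
    return groupings


def _pair_allowed(kind: str, a: pd.Series, b: pd.Series) -> bool:
    if kind == "hemilineage_only":
        return (
            a["temporal_group"] != b["temporal_group"]
            or a["temporal_group"] == "unassigned"
        )
    if kind == "temporal_only":
        return (a["lineage"], a["hemilineage"]) != (b["lineage"], b["hemilineage"])
    return True


def grouping_pair_values(
    metric: pd.DataFrame, grouping: CohortGrouping, annotations: pd.DataFrame | None = None
) -> np.ndarray:
    """Pool the metric values of all eligible within-cohort pairs.

    Cohorts with fewer than two scored members contribute no pairs.  The
    metric matrix is symmetrized and self-pairs are excluded.
    """
    M = 0.5 * (metric + metric.T)
    values = []
    for _, ids in grouping.members.items():
        ids = [i for i in ids if i in M.index]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                if annotations is not None and not _pair_allowed(
                    grouping.kind, annotations.loc[ids[x]], annotations.loc[ids[y]]
                ):
                    continue
                values.append(M.loc[ids[x], ids[y]])
    return np.asarray(values, dtype=float)


@dataclass
class CohortComparisonResult:
    """Summary statistics, pairwise tests and pooled values per grouping."""

    summary: pd.DataFrame
    tests: pd.DataFrame
    values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def cohort_comparison(
    metric: pd.DataFrame,
    groupings: list[CohortGrouping],
    annotations: pd.DataFrame | None = None,
) -> CohortComparisonResult:
    """Compare a pairwise score across developmental groupings.

    For each grouping, eligible within-cohort pair values are pooled and
    summarized (n, mean, median, SEM, one-sample KS normality p).  Each
    pair of groupings is compared with a two-sided Wilcoxon rank-sum test
    (exact for small tie-free samples) and a two-sample Kolmogorov-Smirnov
    test on the empirical distributions.
    """
    values = {
        g.kind: grouping_pair_values(metric, g, annotations=annotations) for g in groupings
    }
    rows = []
    for kind, v in values.items():
        if v.size >= 2 and v.std(ddof=1) > 0:
            normal_p = float(stats.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue)
        else:
            normal_p = np.nan
        rows.append(
            {
                "grouping": kind,
                "n_pairs": int(v.size),
                "mean": float(v.mean()) if v.size else np.nan,
                "median": float(np.median(v)) if v.size else np.nan,
                "sem": float(stats.sem(v)) if v.size >= 2 else np.nan,
                "normality_ks_p": normal_p,
            }
        )
    summary = pd.DataFrame(rows)

    test_rows = []
    kinds = list(values)
    for i in range(len(kinds)):
        for j in range(i + 1, len(kinds)):
            a, b = values[kinds[i]], values[kinds[j]]
            if a.size == 0 or b.size == 0:
                continue
            mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            ks = stats.ks_2samp(a, b)
            test_rows.append(
                {
                    "grouping_a": kinds[i],
                    "grouping_b": kinds[j],
                    "test": "wilcoxon_ranksum",
                    "statistic": float(mw.statistic),
                    "p": float(mw.pvalue),
                    "ks_statistic": float(ks.statistic),
                    "ks_p": float(ks.pvalue),
                }
            )
    tests = pd.DataFrame(
        test_rows,
        columns=["grouping_a", "grouping_b", "test", "statistic", "p", "ks_statistic", "ks_p"],
    )
    return CohortComparisonResult(summary=summary, tests=tests, values=values)


def cumulative_distribution(values: np.ndarray) -> pd.DataFrame:
    """Empirical CDF of pooled pair values, for cumulative plots/exports."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": v, "cdf": np.arange(1, v.size + 1) / v.size})
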
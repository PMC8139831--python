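"""Monte-Carlo null models for connectivity.

The question the nulls answer: do hemilineage-temporal (HL-T) cohorts
connect to each other more often than axon/dendrite proximity alone would
predict (Peter's rule)?  Observed binarized connectivity is compared with
shuffled matrices that preserve each neuron's output degree exactly while
redrawing its targets from a connection-probability model — either
proportional to each target's input degree (degree-based null) or to the
pre/post synapse overlap score (proximity null, optionally thresholded).
The statistic is the frequency with which both members of a within-cohort
pair connect onto a common other cohort; significance is an add-one
empirical p-value over the shuffle distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .core import BinaryConnectivity

FREQUENCY_VARIANTS = ("pair_both", "cohort_pair", "per_neuron")


@dataclass
class ConnectionProbabilityModel:
    """Per-presynaptic-neuron target distributions.

    ``p`` has one row per presynaptic neuron; rows sum to 1 except rows with
    no admissible targets, which are all-zero and flagged in ``zero_rows``.
    """

    mode: str
    p: np.ndarray
    overlap_threshold: float = 0.0
    zero_rows: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.zero_rows is None:
            self.zero_rows = ~(self.p.sum(axis=1) > 0)


def connection_probabilities(
    mode: str,
    matrix: np.ndarray | BinaryConnectivity,
    overlap_threshold: float = 0.0,
) -> ConnectionProbabilityModel:
    """Build a connection-probability model.

    ``mode='input_degree'``: the probability of connecting to a neuron is
    its binarized input degree divided by the total (identical across
    presynaptic neurons, self excluded).  ``mode='overlap'``: proportional
    to the pre/post overlap score, after zeroing entries below
    ``overlap_threshold``; zero-overlap pairs have zero probability.
    """
    if mode not in ("input_degree", "overlap"):
        raise ValueError("mode must be 'input_degree' or 'overlap'")
    M = matrix.matrix if isinstance(matrix, BinaryConnectivity) else matrix
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError("matrix must be square")
    if mode == "input_degree":
        indeg = M.sum(axis=0)
        p = np.tile(indeg, (n, 1))
    else:
        p = M.copy()
        p[p < overlap_threshold] = 0.0
    np.fill_diagonal(p, 0.0)
    p = np.clip(p, 0.0, None)
    mass = p.sum(axis=1, keepdims=True)
    zero = mass[:, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(zero[:, None], 0.0, p / np.where(mass > 0, mass, 1.0))
    return ConnectionProbabilityModel(
        mode=mode, p=p, overlap_threshold=float(overlap_threshold), zero_rows=zero
    )


def shuffle_connectivity(
    binary: np.ndarray | BinaryConnectivity,
    model: ConnectionProbabilityModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Degree-preserving shuffle of a binarized connectivity matrix.

    For each presynaptic neuron with output degree ``d``, ``d`` distinct
    targets are drawn without replacement from its model row, so output
    degrees are preserved exactly in every replicate.

    Raises
    ------
    ValueError
        If a neuron has fewer admissible (nonzero-probability) targets than
        its output degree; lowering the overlap threshold admits more.
    """
    B = binary.matrix if isinstance(binary, BinaryConnectivity) else binary
    B = np.asarray(B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = B.shape[0]
    out = np.zeros_like(B, dtype=np.int8)
    degrees = B.sum(axis=1)
    for i in range(n):
        d = int(degrees[i])
        if d == 0:
            continue
        row = model.p[i]
        admissible = int(np.count_nonzero(row))
        if admissible < d:
            raise ValueError(
                f"neuron index {i}: out-degree {d} but only {admissible} admissible "
                "targets under the model (consider lowering the overlap threshold)"
            )
        targets = rng.choice(n, size=d, replace=False, p=row)
        out[i, targets] = 1
    return out


@dataclass(frozen=True)
class FrequencyResult:
    """A cohort connection frequency with its combinatorial universe."""

    frequency: float
    n_successes: int
    n_combinations: int
    variant: str

    def __float__(self) -> float:
        return self.frequency


def cohort_connection_frequency(
    binary: np.ndarray | BinaryConnectivity,
    cohorts: dict[str, list[int]] | dict[str, list[str]],
    variant: str = "pair_both",
) -> FrequencyResult:
    """Frequency of coordinated cohort-to-cohort connectivity.

    Under the default ``pair_both`` reading, the universe is every
    (unordered within-cohort neuron pair, other cohort C) combination, and
    a combination succeeds when *both* pair members have at least one
    outgoing connection into C.  Cohorts with fewer than two members
    contribute no pairs.  Alternative readings (for sensitivity analyses):
    ``cohort_pair`` counts ordered cohort pairs (A, C) with at least one
    coordinated within-A pair, and ``per_neuron`` counts (member, C)
    combinations with any connection.  The chosen reading travels with the
    result.
    """
    if variant not in FREQUENCY_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(binary, BinaryConnectivity):
        index = {nid: k for k, nid in enumerate(binary.neuron_ids)}
        B = np.asarray(binary.matrix, dtype=bool)
        cohort_idx = {
            label: np.array([index[str(i)] for i in ids], dtype=int)
            for label, ids in cohorts.items()
        }
    else:
        B = np.asarray(binary, dtype=bool)
        cohort_idx = {label: np.asarray(ids, dtype=int) for label, ids in cohorts.items()}

    labels = list(cohort_idx)
    K = len(labels)
    # reach[i, c]: neuron i has >= 1 outgoing edge into cohort c
    member_mat = np.zeros((B.shape[0], K), dtype=bool)
    for c, label in enumerate(labels):
        member_mat[cohort_idx[label], c] = True
    reach = B @ member_mat

    successes = 0
    total = 0
    for a, label in enumerate(labels):
        idx = cohort_idx[label]
        m = idx.size
        others = [c for c in range(K) if c != a]
        if variant == "per_neuron":
            successes += int(reach[np.ix_(idx, others)].sum())
            total += m * len(others)
            continue
        if m < 2:
            continue
        r = reach[np.ix_(idx, others)].sum(axis=0)  # members reaching each other cohort
        pairs_both = np.array([comb(int(x), 2) for x in r])
        if variant == "pair_both":
            successes += int(pairs_both.sum())
            total += comb(m, 2) * len(others)
        else:  # cohort_pair
            successes += int((pairs_both > 0).sum())
            total += len(others)
    if total == 0:
        raise ValueError("no eligible (pair, cohort) combinations")
    return FrequencyResult(
        frequency=successes / total,
        n_successes=successes,
        n_combinations=total,
        variant=variant,
    )


@dataclass
class NullResult:
    """Observed statistic, shuffle samples and add-one empirical p-value."""

    observed: FrequencyResult
    samples: np.ndarray
    p_value: float
    n_iter: int
    seed: int | None
    model_mode: str
    overlap_threshold: float

    def manifest(self) -> dict:
        return {
            "mode": self.model_mode,
            "overlap_threshold": self.overlap_threshold,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "observed": self.observed.frequency,
            "variant": self.observed.variant,
            "p": self.p_value,
        }


def null_distribution(
    binary: np.ndarray | BinaryConnectivity,
    model: ConnectionProbabilityModel,
    cohorts: dict,
    n_iter: int = 1000,
    seed: int | None = None,
    variant: str = "pair_both",
) -> NullResult:
    """Empirical null of the cohort connection frequency under shuffles.

    The add-one convention ``p = (1 + #{samples >= observed}) / (n_iter + 1)``
    keeps p strictly inside (0, 1].
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a meaningful empirical p")
    B = binary.matrix if isinstance(binary, BinaryConnectivity) else binary
    B = np.asarray(B)
    if isinstance(binary, BinaryConnectivity):
        index = {nid: k for k, nid in enumerate(binary.neuron_ids)}
        cohorts = {
            label: [index[str(i)] for i in ids] for label, ids in cohorts.items()
        }
    observed = cohort_connection_frequency(B, cohorts, variant=variant)
    rng = np.random.default_rng(seed)
    degrees = B.sum(axis=1)
    samples = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = shuffle_connectivity(B, model, seed=rng)
        assert (shuffled.sum(axis=1) == degrees).all(), "output degrees must be preserved"
        samples[it] = cohort_connection_frequency(shuffled, cohorts, variant=variant).frequency
    p = (1.0 + float((samples >= observed.frequency).sum())) / (n_iter + 1.0)
    return NullResult(
        observed=observed,
        samples=samples,
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        model_mode=model.mode,
        overlap_threshold=model.overlap_threshold,
    )
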
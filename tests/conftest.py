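import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lineagecircuits as lc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def calibration_config(seed: int, hlt_bonus: float, **overrides) -> lc.GeneratorConfig:
    """Scaled-down study conditions used for null-model calibration runs:
    3 lineages x 2 hemilineages x 3 temporal groups x 4 neurons per cohort,
    no sensory/motor populations, single-hemisegment analysis downstream."""
    kwargs = dict(
        n_lineages=3,
        temporal_groups_per_hemilineage=3,
        neurons_per_hlt=4,
        n_sensory_per_side=0,
        n_motor_per_side=0,
        hlt_bonus=hlt_bonus,
        seed=seed,
    )
    kwargs.update(overrides)
    return lc.GeneratorConfig(**kwargs)


def left_interneuron_binary(connectome, threshold=1):
    """Binarized left-hemisegment interneuron connectivity + cohort map."""
    ann = connectome.annotations
    left = ann[(ann["hemisegment"] == "left") & (ann["cell_class"] == "interneuron")]
    ids = list(left["neuron_id"])
    binary = lc.binarize(lc.build_connectivity(connectome.connectors, ids), threshold)
    cohorts = lc.hlt_cohorts(ann, hemisegment="left")
    return binary, cohorts


@pytest.fixture(scope="session")
def default_connectome():
    """The default synthetic connectome (7 lineages x 2 HL x 4 T x 3)."""
    return lc.generate_connectome(lc.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_connectome():
    """A compact bilateral connectome with sensory/motor populations."""
    return lc.generate_connectome(
        lc.GeneratorConfig(
            n_lineages=3,
            temporal_groups_per_hemilineage=2,
            neurons_per_hlt=3,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_tree_skeleton(rng, n_nodes=30, neuron_id="rand"):
    """A random rooted tree with uniformly scattered 3D nodes (nm scale)."""
    coords = rng.uniform(-10000, 10000, (n_nodes, 3))
    parents = np.full(n_nodes, -1, dtype=int)
    for k in range(1, n_nodes):
        parents[k] = rng.integers(0, k)  # parent precedes child
    node_ids = np.arange(1, n_nodes + 1)
    parent_ids = np.where(parents < 0, -1, node_ids[np.maximum(parents, 0)])
    return lc.Skeleton(
        neuron_id=neuron_id,
        node_ids=node_ids,
        parent_ids=parent_ids,
        coords=coords,
        radii=np.full(n_nodes, 100.0),
    )
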
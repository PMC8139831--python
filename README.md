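# lineagecircuits

Tools for asking how a neuron's developmental origin shapes its place in a
circuit, at the resolution of single synapses.

In the insect ventral nerve cord, every neuron descends from an identified
neuroblast. Each neuroblast lineage splits into a **dorsal and a ventral
hemilineage** (by Notch state of sibling neurons), and within a hemilineage
neurons are born in sequence under a temporal transcription-factor series
(Hb → Kr → Pdm → Cas). The intersection of a hemilineage with a birth-time
window — a **hemilineage-temporal (HL-T) cohort** — is a candidate unit of
circuit assembly: its members may share neuropil targeting, synapse
placement, and synaptic partners. This package implements the computational
side of that question for synapse-resolution connectomes (SWC skeletons +
polyadic connector tables), together with a ground-truth-labelled synthetic
connectome generator so that every stage can be validated without any
reconstruction data.

## What it computes

**Synapse similarity.** For neurons *i*, *j*, each synapse *s* of *i* is
matched to its nearest synapse *k* of *j* and scored

```
f(is, jk) = exp(-d_sk² / 2σ²) · exp(-|n_is - n_jk| / (n_is + n_jk))
```

where `d_sk` is their Euclidean distance and `n_is`, `n_jk` are the local
synapse-density fractions within a radius ω (defaults σ = ω = 2000 nm). The
directed score is the mean of *f*; applied between the *presynapses* of one
neuron and the *postsynapses* of another it becomes a pre/post **overlap**
score — a proximity proxy for potential connectivity (Peter's rule).

**Morphometric proxies of birth order.** Cortex neurite length (geodesic
soma → neuropil-entry distance along the skeleton) is binned into four
temporal groups using cut points fitted from reference populations of
identified early (Hb+) and late (Cas+) neurons: `t1 = mean(Hb) + sd(Hb)`,
`t2 = mean(Cas) − sd(Cas)`, `t3 = mean(Cas)`. Hemilineages are recovered
from skeleton morphology: Strahler pruning of distal twigs, resampled
dotprops with local tangents, a Gaussian × |tangent dot| similarity kernel,
and average-linkage clustering per lineage.

**Connectivity statistics.** Contact-count matrices from polyadic
connectors (one count per postsynaptic partner), binarization, cosine
similarity of binarized input/output vectors, direction-blind synaptic
network distance, premotor/postsensory classification, and rank-sum /
Kolmogorov–Smirnov comparisons of pairwise scores across developmental
groupings (unrelated, temporal-only, hemilineage-only, HL-T).

**Null models.** Degree-preserving Monte-Carlo shuffles in which each
neuron keeps its output degree but redraws targets with probability
proportional to either target input degree or pre/post overlap (optionally
thresholded). The test statistic is the frequency with which both members
of a within-cohort pair connect onto a common other cohort; significance is
an add-one empirical p-value.

## Worked example

```python
import numpy as np
import lineagecircuits as lc

config = lc.GeneratorConfig(n_lineages=3, temporal_groups_per_hemilineage=2,
                            neurons_per_hlt=3, seed=7)
connectome = lc.generate_connectome(config)
ann = connectome.annotations

# birth order from geometry: cortex neurite length -> temporal group
neuron = "NB1-d-T2-0-L"
length = lc.cortex_neurite_length(connectome.skeletons[neuron], config.neuropil)
bins = lc.fit_temporal_bins(connectome.reference_lengths["hb"],
                            connectome.reference_lengths["cas"])
group = lc.assign_temporal_group(length, bins)

# synapse similarity: same cohort vs unrelated
syns = lc.synapses_from_connectors(connectome.connectors)
same = lc.synapse_similarity(syns["NB1-d-T2-0-L"]["pre"], syns["NB1-d-T2-1-L"]["pre"])
diff = lc.synapse_similarity(syns["NB1-d-T2-0-L"]["pre"], syns["NB3-d-T1-0-L"]["pre"])

# is cohort-to-cohort connectivity above the proximity expectation?
left = ann[(ann.hemisegment == "left") & (ann.cell_class == "interneuron")]
ids = list(left["neuron_id"])
binary = lc.binarize(lc.build_connectivity(connectome.connectors, ids), 2)
pre = {n: syns.get(n, {}).get("pre", np.empty((0, 3))) for n in ids}
post = {n: syns.get(n, {}).get("post", np.empty((0, 3))) for n in ids}
model = lc.connection_probabilities("overlap", lc.overlap_matrix(pre, post).to_numpy())
null = lc.null_distribution(binary, model, lc.hlt_cohorts(ann, "left"),
                            n_iter=500, seed=0)
```

This prints:

```
108 neurons, 958 connectors
NB1-d-T2-0-L: cortex neurite length 15849 nm -> temporal group 2
presynapse similarity, same HL-T cohort: 0.539; other lineage: 0.000
observed HL-T connection frequency 0.159, proximity-null p = 0.0060
```

Read top to bottom: the neuron's soma sits 15.8 µm from its neuropil entry
point, placing it in the second birth-order group (its true generated label);
its presynapse cloud nearly coincides with a cohort-mate's but not with a
neuron from another lineage; and cohort-to-cohort connectivity in this
connectome (generated with a cohort wiring bonus) is higher than the
degree-preserving proximity shuffle can explain.

The same analyses are available from the shell:

```bash
lineagecircuits generate --seed 1 --out fixtures/
lineagecircuits run-all fixtures/ --out results/run1
```

which writes `report.json`, per-neuron length and cluster tables,
similarity matrices, density-map grids and null-model samples.

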
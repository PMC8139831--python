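# Methods

This note documents the models and procedures implemented in
`lineagecircuits`, the defaults and why they were chosen, what the
synthetic connectome generator does and does not emulate, and the numerical
decisions a user should know before trusting a result.

## Data model

All coordinates are nanometres; axes are fixed as x = mediolateral,
y = dorsoventral (dorsal = +y), z = anteroposterior. Skeletons are rooted
trees with the soma at the root (SWC, parent −1 = root). A *connector* is
one presynaptic site with ≥1 postsynaptic partner sites; a polyadic synapse
therefore contributes one contact per partner everywhere contacts are
counted. Autapses are rejected at load (logged), which keeps the
contact-count matrix diagonal identically zero. Connector rows naming
neurons absent from the analysis set are dropped with a logged count, since
real reconstructions cover a traced subset of a larger volume.

## Synapse similarity and pre/post overlap

For synapse *s* of neuron *i* with nearest synapse *k* of neuron *j*:

    f(is, jk) = exp(−d_sk² / 2σ²) · exp(−|n_is − n_jk| / (n_is + n_jk))

`n_is` (`n_jk`) is the fraction of neuron *i*'s (*j*'s) synapses within ω
of *s* (*k*). The directed score is the mean of *f* over the synapses of
*i*; a symmetric variant averages the two directions. Defaults
σ = ω = 2000 nm.

Decisions:

- **The ω-ball includes the anchor synapse itself**, so the density
  fractions are strictly positive, the second factor is always defined, and
  a neuron scored against itself gives exactly 1.
- Nearest-neighbour ties resolve to the lowest index; with continuous
  coordinates ties have measure zero.
- The **overlap score** applies the same kernel between the presynapses of
  one neuron and the postsynapses of another. An empty cloud on either side
  scores 0 by convention (a neuron with no presynapses cannot overlap
  anything); this case is logged, not raised, because sensory and motor
  populations legitimately carry only one polarity.
- Pair scores in group analyses are **bilaterally averaged**: the score of
  a neuron pair is the mean of the left-side and right-side scores of the
  corresponding homolog pairs. A missing side propagates the other side
  with a warning.

Implementation uses KD-trees; the test suite pins it to a nested-loop
brute-force recomputation at 1e-9 on random clouds.

## Density maps

2D Gaussian KDE of synapse positions on the transverse (x, y) projection,
with 1D marginals. Bandwidth defaults to Scott's rule (the choice is
configurable and recorded). The outermost contour is drawn at the density
level whose superlevel set encloses a given fraction of total probability
mass (60% default, 80% for whole-lineage maps) — a *mass-referenced*
contour, not a fraction of peak height; the alternative reading exists in
the literature, and the mass reading was chosen because it is invariant to
peak sharpness. Under the `polyadic` weighting policy each presynaptic site
is weighted by its partner count. An optional anteroposterior window
restricts the synapses used, mirroring the practice of cross-sectioning a
single segment range where the neuropil's shape is consistent. Degenerate
input (all synapses identical) produces a point-mass map with a warning.

## Morphometric proxies of development

**Strahler order.** Leaves have order 1; a parent has order m+1 if two or
more children attain the maximum child order m, else m. `prune_by_strahler`
keeps nodes with order ≥ k (root always kept); the kept set is
automatically root-connected because order is non-increasing rootward. The
morphology-clustering pipeline prunes at k = 2 by default (removes terminal
twigs); the level mainly affects clustering robustness, which the tests
measure directly.

**Cortex neurite length.** The neuropil entry point is the in-volume node
with minimal geodesic distance from the root; cortex neurite length is that
geodesic. It is invariant under node re-indexing and edge subdivision
(tested). Homolog pairs are summarized by the left/right mean.

**Temporal groups.** Cut points from reference populations:
t1 = mean(Hb) + sd(Hb), t2 = mean(Cas) − sd(Cas), t3 = mean(Cas), with
*sample* (n−1) standard deviations, since reference sets are small
empirical samples. Assignment: group 1 iff L < t1; group 2 iff
t1 ≤ L ≤ t2; group 3 iff t2 < L ≤ t3; group 4 iff L > t3 (boundaries owned
by groups 2, 2, 3 respectively, following the strict/inclusive wording of
the binning definitions). Construction fails if t1 > t2 — the references
overlap too much to define four ordered bins.

**Morphology kernel and clustering.** Skeletons are resampled at uniform
arc length (1000 nm default) into dotprops; the tangent at each point is
the dominant principal direction of its k = 5 nearest resampled points
(tangent sign is canonicalized and irrelevant downstream). The similarity
of a query against a target is the mean over query points of
exp(−d²/2σ_n²)·|u·v| with σ_n = 2000 nm, which is the query's raw score
normalized by its self-score (self-similarity ≡ 1, rigid-motion invariant).
This is a deliberately analytic, self-contained kernel: it is monotone in
the same geometric quantities as empirical log-odds morphology scorers but
requires no external scoring matrices. Per-lineage clustering uses
average linkage on 1 − (S + Sᵀ)/2 cut at height 0.9; the default cutoff was
calibrated once on the synthetic two-hemilineage geometry, where
within-hemilineage merge heights (~0.6–0.75) and the dorsal/ventral merge
(~1.0) leave a wide stable band, and any cutoff in that band yields exactly
two clusters.

## Connectivity statistics

- Binarization at an explicit threshold (2 contacts by default for
  null-model analyses); the threshold travels with the matrix.
- Premotor/postsensory: strictly more than 3 contacts onto a *single*
  motor neuron (respectively from a single sensory neuron). The singular
  reading is the default; an aggregate-over-all-partners variant is behind
  `per_partner=False`.
- Connectivity similarity: cosine similarity of binarized output rows or
  input columns; all-zero vectors score 0 and are flagged.
- Network distance: shortest path length in the *undirected* binarized
  graph — neurons sharing a common input or output are two synapses apart,
  which forces the direction-blind reading; unreachable pairs are ∞.
- Cohort comparisons: within-cohort pair values pooled per grouping.
  `hemilineage_only` pools exclude same-temporal pairs and `temporal_only`
  pools exclude same-hemilineage pairs, so the coarser groupings measure
  what the finer ones do not. The unrelated baseline is random
  pseudo-cohorts drawn within a hemisegment. Normality is pre-checked with
  a one-sample Kolmogorov–Smirnov test; group differences use the
  two-sided Wilcoxon rank-sum (exact for small tie-free samples, as in the
  {1,2,3} vs {101,102,103} enumeration check, p = 0.1) and two-sample KS on
  the empirical distributions. Cohorts with fewer than two scored members
  contribute no pairs.

## Null models

Connection-probability models (per presynaptic row, normalized to 1):

- `input_degree`: probability proportional to each target's binarized
  input degree, identical across rows, self excluded.
- `overlap`: proportional to the pre/post overlap score after zeroing
  entries below a threshold; zero-overlap pairs can never be drawn.

A shuffle preserves every neuron's output degree exactly: d distinct
targets are drawn *without replacement* from the model row (a binarized
matrix cannot host duplicate edges). The statistic is the **cohort
connection frequency**: over all unordered within-cohort pairs (m, n) and
all other cohorts C, the fraction of combinations where both m and n have
at least one outgoing edge into C. This reading (`pair_both`) is recorded
in the result; two alternative readings (`cohort_pair` existence,
`per_neuron` membership) are implemented behind a flag for sensitivity
analyses because the combinatorial universe of the statistic admits more
than one construction. Empirical significance uses the add-one convention
p = (1 + #{samples ≥ observed}) / (n_iter + 1), which can never return 0.

## The synthetic connectome generator

The generator emulates the statistical structure the analyses assume, with
known labels:

- **Bilateral hemisegments.** The right side is the x-mirrored left side
  with Gaussian jitter (σ = 250 nm) on every coordinate; homolog pairs are
  exact. Jitter is prevented from moving a skeleton node across the
  neuropil boundary so the entry point (and hence cortex length) of the
  mirrored neuron stays well defined.
- **Radial cortex layering.** Each neuron's cortex neurite is a collinear
  three-segment path of exactly its intended length from the soma (outside
  the neuropil) to an entry node on the neuropil face. Intended lengths are
  drawn per temporal group around the bin centers implied by the reference
  distributions (Hb: 8000 ± 1500 nm; Cas: 30000 ± 4000 nm; 40 reference
  cells per population), clipped to stay min(2000 nm, 45% of bin width)
  clear of the bin boundaries. The margin was sized from an a priori error
  propagation: cut points refitted from 40-cell reference samples have
  standard errors of a few hundred nm, well inside the margin, so group
  recovery is limited by the procedure, not by boundary noise.
- **Hemilineage anatomy.** Each lineage has a dorsal (+y) and a ventral
  (−y) anchor; all neurons of a hemilineage route through a shared trunk
  from their entry point to the anchor (the hemilineage's neurite bundle)
  before branching at their cohort-specific arbor — this shared trunk is
  what makes hemilineages morphologically coherent units, and it is what
  the clustering recovers.
- **Synapse clouds.** Each HL-T cohort concentrates its signature polarity
  (presynapses for dorsal, postsynapses for ventral cohorts) in a
  cohort-specific isotropic Gaussian (σ = 1500 nm) on a ring around the
  anchor; the opposite polarity is spread diffusely over the hemilineage
  territory (5× the cluster spread). Real synapse clouds are irregular;
  only relative clustering is analytically relevant. Sensory neurons carry
  purely ventral presynapses and motor neurons purely dorsal postsynapses.
- **Connectivity.** Baseline wiring follows exactly the generative law of
  the proximity null: each neuron draws an output degree ~
  Poisson(10) and samples that many distinct targets with probability
  proportional to cloud-level pre/post overlap. With a cohort bonus ε > 0,
  *additional* edges appear on designated HL-T cohort pairs with
  probability min(0.5, ε · 10 · overlap share), so the expected connection
  rate on those pairs is proportional to overlap × (1 + ε) up to the cap.
  This construction makes the ε = 0 ground truth exchangeable with the
  degree-preserving shuffle by design (type-I error testing is then
  well-posed), and makes ε > 0 an addition *above* the proximity
  expectation rather than a reallocation the null would reproduce.
- **Designated pairs** are drawn from cohort pairs whose mean overlap
  share lies in [0.002, 0.05]: zero-share pairs cannot gain
  overlap-proportional edges, and top-share pairs are already connected by
  proximity, leaving no headroom above the null. 30% of ordered cohort
  pairs are designated (bounded by the eligible band).
- Each realized edge carries 1 + Poisson(1) contacts; contacts are grouped
  into polyadic connectors with partner counts 1 + Poisson(polyadic_mean −
  1). Connector pre-locations and partner post-locations are fresh draws
  from the owning neuron's cloud distributions.

Everything derives from one seed; identical configs produce byte-identical
fixture files.

**What the generator does not emulate**, and therefore what passing tests
do not show about real data: neurite tortuosity and realistic branching
statistics; spatial association between a connector and its partner sites
(pre and post positions of one contact are independent draws from the two
neurons' clouds); contralateral connectivity (the two hemisegments are
wired independently); size and strength heterogeneity across lineages;
glial hemilineages; and any activity-dependent refinement. Analyses that
depend only on relative spatial statistics and degree structure transfer;
claims about absolute score magnitudes do not.

## Problem sizes and calibration conditions

The default connectome is 7 lineages × 2 hemilineages × 4 temporal groups
× 3 neurons per cohort × 2 sides plus 10 sensory and 8 motor neurons per
side (372 neurons) — the scale at which label-recovery tests run. The
null-model calibration uses a more compact design chosen for Monte-Carlo
throughput with a larger cohort count per neuron: 3 lineages × 2
hemilineages × 3 temporal groups × 4 neurons per cohort, no sensory/motor
cells, analysed on one hemisegment (72 interneurons, 18 cohorts), with 500
shuffles per run and 50 generator seeds per condition. In calibration runs
the null model is conditioned on the generator's synapse site clouds rather
than the realized synapse multisets: with only tens of realized synapses
per neuron, the overlap estimate itself carries enough noise to distort the
type-I check, and the calibration is meant to validate the shuffle
machinery, not the overlap estimator. The pipeline's default on data
(including the acceptance script's default-connectome run) conditions on
realized synapse positions, exactly as one must with a reconstruction.

## Known limitations

- The overlap estimated from realized synapses is noisy at low synapse
  counts; empirical p-values from the realized-cloud null on very small
  connectomes should be treated as approximate.
- Weighted sampling without replacement has inclusion probabilities that
  deviate from raw weights by a few percent at moderate sampling fractions
  (noncentral hypergeometric bias); the input-degree proportionality
  property is therefore exact only in the sparse regime.
- The morphology kernel is analytic, not trained; it recovers coherent
  morphological classes but its absolute scores are not comparable to
  empirical log-odds scorers.
- Mesh neuropil volumes are supported through trimesh containment tests
  but the generator itself requires an axis-aligned box.

## Pipeline report

`run_pipeline` writes `report.json` (schema in
`docs/report_schema.json`), with all floats serialized at 12 significant
digits so identical runs produce identical bytes, alongside per-neuron
length and cluster tables, similarity matrices, density-map grids,
cohort-comparison tables and null-model samples.
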
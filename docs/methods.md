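# Methods

## The model

`stgat` is a graph attention auto-encoder over a spatial neighbor network
(SNN). Spots are nodes; edges connect spatially proximal spots; self-loops
are always included so a spot's own expression participates in its
neighborhood aggregate. The encoder maps normalized log expression to a
30-dimensional embedding through a 512-unit attention-bearing layer; the
decoder mirrors it with tied weights (each decoder weight is the transpose
of the corresponding encoder weight — a view, never a copy, so the tie
holds after every optimizer step by construction) and reuses the encoder's
attention map. Only the middle layers aggregate over neighbors; the final
encoder and decoder layers are plain affine maps through the ELU
nonlinearity. The training objective is the summed squared per-spot
reconstruction error of the normalized expression.

Assumptions worth keeping in mind:

* **Spatial coherence.** The inductive bias is that neighboring spots tend
  to share expression programs; attention lets the model down-weight
  neighbors across a domain boundary, but a tissue with no spatial
  organization gains nothing from the graph.
* **Per-edge attention is normalized per receiving spot** (softmax over the
  spot's neighbor set, self-loop included), so each spot's incoming weights
  form a convex combination. The printed form of the softmax denominator in
  the source method is index-ambiguous; normalizing over the receiving
  spot's neighbors is the only reading that yields a per-spot distribution,
  and it is what we implement.
* **Squared vs plain norm.** The loss is implemented as the squared
  Euclidean norm summed over spots (the standard auto-encoder choice,
  smooth at zero). The plain unsquared norm is available via
  `TrainingConfig(loss="norm")`; both have the same optimum at perfect
  reconstruction.
* **Full-batch training.** Each "iteration" is one gradient step on the
  whole graph. Gradients flow through the attention scores (attention is
  part of the computation graph, not a detached heuristic).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `k` (kNN graph) | 6 | hexagonal-lattice neighborhood of Visium-like chips |
| `r` (radius graph) | user-chosen | pick so spots average 6–15 neighbors |
| encoder widths | 512, 30 | hidden and embedding dimension |
| learning rate | 1e-4 | Adam, full batch |
| weight decay | 1e-4 | L2-coupled (added to the gradient, torch-style) |
| iterations | 500 / 1000 | 1000 when the aware module is active |
| α (aware blend) | 0.5 | weight of the pruned-graph attention |
| pre-cluster resolution | 0.2 | Louvain on 50 PCs, kNN-15 graph |
| HVG count | 3000 | mean-binned normalized dispersion (seurat flavor) |
| marker FDR | 0.01 | Benjamini–Hochberg within each domain's gene list |

Graph construction details that matter for exactness: the radius rule is a
strict inequality (distance exactly `r` is *not* an edge); the kNN relation
is symmetrized by union, and ties at the k-th distance break by spot index
for determinism. The aware pruning keeps an edge only when both endpoints
share a pre-cluster; self-loops always survive, so the pruned edge set is a
subset of the SNN's and attention stays well defined. Attention on edges
pruned away receives only the `(1−α)` spatial share. The aware module is
off by default: it is meant for low-resolution chips where one spot mixes
cell types; at cellular/subcellular resolution pre-clusters are noisy and
pruning does more harm than good.

For multi-section stacks, the 3D SNN places each section's 2D SNN on the
block diagonal and bridges *adjacent* sections only, linking spots whose
in-plane distance (z offset ignored) is below `inter_section_radius`
(default: the 2D radius, or 1.5× the median nearest-neighbor spacing in
kNN mode). Coordinates must already be aligned across sections; alignment
itself is out of scope. Highly variable genes are selected jointly across
sections by default.

## Numerical core

No deep-learning framework is used: the model runs on a compact
reverse-mode autodiff tape (`stgat._autograd`) over NumPy arrays and
constant SciPy sparse operators, with neighborhood aggregation fused into a
single sparse-matrix product per layer, plus a hand-written Adam. Every
op's gradient is validated against central finite differences in the test
suite (relative error ~1e-7), and the sparse edge-wise forward pass is
validated against an independent dense attention-matrix oracle on small
random instances. Parameters are initialized Glorot-uniform from a seeded
generator; runs are bit-reproducible for a fixed seed on a fixed BLAS.
Raw attention scores pass through a sigmoid, so they lie in (0, 1) and the
softmax needs no max-shift for stability. Training aborts with a
diagnostic if the loss turns non-finite. The aware-mode 1000-iteration run
is a single phase with blending active from the start (no spatial-only
warm start).

## Clustering and statistics

When the number of domains is known we fit a seeded Gaussian mixture with a
shared (tied) covariance on the embeddings — a deterministic surrogate for
R-style model-based clustering, which the workflow only ever uses at fixed
k; cross-language parity of a model-search procedure is deliberately not
attempted. Otherwise, Louvain communities on a union-symmetrized kNN graph
(k = 15) of the embeddings, resolution chosen by the user. Markers use a
one-vs-rest Wilcoxon rank-sum test per gene (scipy, tie-corrected
asymptotics, exact for tiny groups) with BH adjustment applied within each
domain's gene list (pooled adjustment available via a flag). Moran's I uses
the SNN adjacency minus its diagonal as binary weights; self-loops would
only add a constant and are excluded by convention.

## The synthetic-tissue generator

The generator emulates the benchmark structure of real platforms: hex
lattices with unit spacing (each interior spot has exactly six equidistant
neighbors, matching the k = 6 rule), square grids, or uniform-random spot
placement; contiguous domains as horizontal layers, concentric rings, or a
thin arc plus V-shaped band over background (hippocampal cord/arrow-like
shapes); and counts drawn negative-binomial with variance m + φm²
(φ = 0.5 by default — typical UMI overdispersion) from per-gene log-normal
baseline means, per-domain marker blocks with a 2.0 log2 fold change
(50 markers per domain of 200 genes in the reference tissue), and per-spot
library sizes log-uniform in [0.5, 2].

The baseline mean scale is 0.1 counts per gene per spot, which yields ~84%
zero entries — the sparsity regime of real Visium/Slide-seq count matrices
restricted to variable genes. This choice is load-bearing: at unrealistic
sequencing depth the layers are separable from per-spot expression alone
and any spatial method's advantage vanishes; at realistic sparsity
per-spot clustering degrades while graph aggregation (≈7 spots per
neighborhood) recovers the signal, reproducing the qualitative gap between
spatial and non-spatial methods observed on real tissue. Multi-section
mode replicates the geometry per section, multiplies every gene's mean by
a per-section log-normal factor (sd 0.4 in the reference stack — a
moderate technical batch shift), and never alters domain labels, so
cross-section consistency has a known ground truth. The dropout corruption
zeroes nonzero entries independently (or binomially thins counts).

What the generator does *not* emulate: gene–gene correlation beyond the
domain programs, spatially smooth within-domain gradients, cell-type
mixtures within a spot, segmentation noise, or histology. Passing tests
therefore show the machinery is correct and the spatial inductive bias
works as designed — not that real-tissue accuracy matches any particular
published benchmark.

## Problem sizes used in tests and the acceptance script

The reference tissue is 1000 spots × 200 genes with three layers; the
domain-recovery check trains five seeds (script: three) at the full 500
iterations and compares Gaussian-mixture clustering of the embeddings
against the same clustering on a 30-component PCA of the identical matrix.
Denoising uses the same tissue with 60% dropout (spots emptied entirely by
the corruption are removed, as empty barcodes would be); the 3D check uses
three 350-spot sections. These sizes are chosen so the full suite runs
comfortably on a single CPU core while keeping every model default at its
reference value.

## Known limitations

* Full-batch training holds the whole graph and dense expression matrix in
  memory; very large sections would need subgraph mini-batching, which is
  not implemented.
* Intra- and inter-section edges of the 3D SNN are treated identically;
  there is no edge typing.
* The Gaussian-mixture surrogate does not reproduce R `mclust`'s model
  selection; it assumes k is given.
* Radius/kNN graphs use Euclidean distance in chip units; no account is
  taken of anisotropic spot spacing.
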
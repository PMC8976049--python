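# stgat

Spatial transcriptomics assigns gene expression profiles to *spots* — fixed
capture locations on a tissue section. Identifying *spatial domains*
(contiguous regions with coherent expression, such as cortical layers) from
these data is hard because per-spot counts are shallow and noisy, and
clustering expression alone ignores where the spots sit. `stgat` learns
low-dimensional spot embeddings with a **graph attention auto-encoder** that
fuses expression similarity with spatial proximity, and uses them for

* spatial-domain identification (clustering the embeddings),
* expression denoising (the decoder's reconstruction), and
* consistent 3D domain extraction across stacks of serial sections.

It is a library for interactive analysis from Python, with a thin `stgat`
command-line interface for end-to-end runs, and ships a synthetic-tissue
generator so every capability is testable with known ground truth.

## Model

Spots are connected in a **spatial neighbor network (SNN)**: an undirected
graph with an edge whenever two spots are within a radius *r* (strictly), or
the union-symmetrized *k* nearest neighbors (*k* = 6 reproduces the
hexagonal Visium neighborhood); self-loops are always present. With
normalized log expression `x_i` as the input embedding `h_i^(0)`, the
encoder layers (default widths 512 → 30) compute

    h_i^(k) = σ( Σ_{j ∈ S_i} att_ij^(k) · W_k h_j^(k-1) )     k < L
    h_i^(L) = σ( W_L h_i^(L-1) )                               (no attention)

with σ = ELU and per-edge attention learned from the incident spots:

    e_ij   = Sigmoid( v_sᵀ (W_k h_i) + v_rᵀ (W_k h_j) )
    att_ij = softmax over j ∈ S_i of e_ij                      (sums to 1 per spot)

The decoder mirrors the encoder with **tied weights** (Ŵ_k = W_kᵀ) and
reuses the encoder's attention, ending in an attention-free output layer
whose result `ĥ_i^(0)` is the reconstructed (denoised) expression. Training
minimizes the reconstruction error Σ_i ‖x_i − ĥ_i^(0)‖² by full-batch Adam
(learning rate 1e-4, weight decay 1e-4, 500 iterations by default).

An optional **cell type-aware** module pre-clusters expression (Louvain at
resolution 0.2 on PCA), prunes SNN edges that cross pre-cluster boundaries,
normalizes attention over the pruned neighborhoods too, and blends the two
maps: `att = (1−α)·att_spatial + α·att_aware` (α = 0.5, 1000 iterations).
For multi-section stacks, a **3D SNN** unions the per-section 2D graphs with
bridges between in-plane-close spots of adjacent sections, which suppresses
per-section batch effects.

Downstream, domains come from a seeded Gaussian mixture (tied covariance)
when the number of domains is known or Louvain otherwise, markers from a
one-vs-rest Wilcoxon test with Benjamini–Hochberg control at 1% FDR, and
spatial coherence is quantified by Moran's I over the SNN.

## Worked example

```bash
python examples/01_spatial_domains.py
```

```
simulated 400 spots x 120 genes, 84% zeros
spatial graph: 6.3 neighbors per spot on average
training loss 4540 -> 3312
ARI vs ground-truth layers: 0.992
```

The simulated tissue has three horizontal layers, each with a block of
marker genes raised 4-fold, at Visium-like sparsity (~84% zero counts).
After 300 training iterations, Gaussian-mixture clustering of the
30-dimensional embeddings reproduces the layer assignment almost perfectly
(adjusted Rand index 0.992; 1.0 is identical, 0 is chance). The other
examples demonstrate denoising (`02`, marker-gene Moran's I rises from
0.013 to 0.796 after 60% dropout), 3D stacking (`03`, domain ARI 1.000 with
the 3D graph vs 0.391 for independent per-section runs), and the aware
module plus marker calling (`04`).

The same workflow is available from a shell:

```bash
stgat simulate --n-spots 1000 --seed 1 --out data/
stgat run --input data/ --n-domains 3 --seed 1 --out results/
```

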
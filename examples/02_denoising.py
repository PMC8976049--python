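"""Denoise dropout-corrupted expression via the decoder reconstruction.

Zeroes 60% of the nonzero counts, trains the auto-encoder on the corrupted
matrix, and shows that the reconstruction restores the spatial coherence
of marker genes (higher Moran's I than the corrupted input).
"""

import numpy as np

import stgat
from stgat.downstream import morans_i
from stgat.model import TrainingConfig, train
from stgat.synthetic import marker_gene_names

spec = stgat.SyntheticSpec(n_spots=400, n_genes=120, n_marker_genes=30, seed=0)
raw, truth = stgat.generate(spec)
corrupted = stgat.corrupt_dropout(raw, rate=0.6, seed=0)
print(f"dropout: {raw.counts_dense().sum():,} -> "
      f"{corrupted.counts_dense().sum():,} total counts")

corrupted = stgat.drop_empty_spots(corrupted)
expr = stgat.preprocess(corrupted, n_top_genes=spec.n_genes)
snn = stgat.build_knn_snn(corrupted.coords, k=6)
res = train(expr, snn, config=TrainingConfig(n_iterations=300, seed=0))
denoised = stgat.denoised_expression(res.reconstruction)

gidx = {g: i for i, g in enumerate(expr.gene_names)}
before, after = [], []
for genes in marker_gene_names(spec).values():
    for g in genes:
        i = gidx.get(g)
        if i is None or expr.values[:, i].var() == 0:
            continue
        before.append(morans_i(expr.values[:, i], snn))
        after.append(morans_i(denoised.values[:, i], snn))
improved = np.mean(np.array(after) > np.array(before))
print(f"marker-gene Moran's I: median {np.median(before):.3f} (corrupted) "
      f"-> {np.median(after):.3f} (denoised)")
print(f"{improved:.0%} of {len(before)} marker genes gained spatial "
      "autocorrelation — the reconstruction recovers the smooth layer "
      "patterns that dropout destroyed")
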
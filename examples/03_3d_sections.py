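"""Extract consistent 3D domains from a batch-shifted multi-section stack.

Simulates three aligned serial sections with per-section batch effects,
builds the 3D graph (per-section 2D graphs + bridges between adjacent
sections), and compares domain recovery and section mixing against
independent per-section analyses.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import stgat
from stgat.datasets import ExpressionMatrix
from stgat.model import TrainingConfig, train

spec = stgat.SyntheticSpec(
    n_spots=250, n_genes=120, n_marker_genes=30,
    n_sections=3, batch_shift_sd=0.4, seed=0,
)
raw, truth = stgat.generate(spec)
expr = stgat.preprocess(raw, n_top_genes=spec.n_genes)
sections = raw.sections
per = [stgat.build_knn_snn(raw.coords[sections == s], 6) for s in np.unique(sections)]
snn3 = stgat.build_3d_snn(per, raw.coords, sections)
print(f"3D graph over {snn3.n_spots} spots, "
      f"{snn3.mean_degree():.1f} mean neighbors (incl. inter-section bridges)")

res = train(expr, snn3, config=TrainingConfig(n_iterations=300, seed=0))
lab3 = stgat.cluster_gmm(res.embeddings, spec.n_domains, seed=0).labels

joint = np.empty(raw.n_spots, int)
for s in np.unique(sections):
    m = sections == s
    ex = ExpressionMatrix(expr.values[m], expr.gene_names, expr.spot_ids[m])
    r = train(ex, per[s], config=TrainingConfig(n_iterations=300, seed=0))
    joint[m] = stgat.cluster_gmm(r.embeddings, spec.n_domains, seed=0).labels + 10 * s

print(f"domain ARI     3D graph {adjusted_rand_score(truth, lab3):.3f}  "
      f"vs independent 2D {adjusted_rand_score(truth, joint):.3f}")
print(f"section mixing 3D graph {adjusted_rand_score(sections, lab3):.3f}  "
      f"vs independent 2D {adjusted_rand_score(sections, joint):.3f}")
print("the 3D graph links matching spots of neighboring sections, so one "
      "domain keeps one label across the stack and the per-section batch "
      "shift stops masquerading as biology (lower section mixing is better)")
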
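"""From embeddings and reconstructions to domains, markers and statistics.

Clustering of spot embeddings uses either a seeded Gaussian mixture with a
shared (tied) covariance when the number of domains is known — a
model-based-clustering surrogate — or Louvain communities on a kNN graph of
the embeddings when it is not. Marker genes are called per domain by a
one-vs-rest Wilcoxon rank-sum test with Benjamini-Hochberg adjustment
(default 1% FDR). Moran's I quantifies spatial autocorrelation of a
per-spot value over the spatial neighbor network.
"""

from __future__ import annotations

import random
import warnings

import igraph
import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datasets import DomainAssignment, ExpressionMatrix
from .graphs import SpatialNeighborNetwork


def cluster_gmm(
    emb: ExpressionMatrix | np.ndarray, k: int, seed: int = 0
) -> DomainAssignment:
    """Gaussian-mixture domains with ``k`` components, tied covariance.

    Deterministic for a fixed seed; labels are maximum-posterior
    assignments relabeled to contiguous integers.
    """
    x = emb.values if isinstance(emb, ExpressionMatrix) else np.asarray(emb)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of spots ({n})")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="tied",
        random_state=seed,
        n_init=5,
        reg_covar=1e-4,
        max_iter=300,
    )
    labels = gm.fit_predict(x)
    return DomainAssignment(labels, method="gmm", params={"k": k, "seed": seed})


def cluster_louvain(
    emb: ExpressionMatrix | np.ndarray,
    resolution: float = 1.0,
    k_graph: int = 15,
    seed: int = 0,
) -> DomainAssignment:
    """Louvain communities on a union-symmetrized kNN graph of embeddings."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x = emb.values if isinstance(emb, ExpressionMatrix) else np.asarray(emb)
    n = x.shape[0]
    k = min(k_graph, n - 1)
    if k < 1:
        return DomainAssignment(np.zeros(n, int), method="louvain")
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    a = nn.kneighbors_graph(x, mode="connectivity")
    a = a.maximum(a.T).tocoo()
    mask = a.row < a.col
    g = igraph.Graph(n=n, edges=list(zip(a.row[mask].tolist(), a.col[mask].tolist())))
    state = random.getstate()
    try:
        random.seed(seed)
        part = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    return DomainAssignment(
        np.asarray(part.membership, int),
        method="louvain",
        params={"resolution": resolution, "k_graph": k_graph, "seed": seed},
    )


def rank_markers(
    expr: ExpressionMatrix,
    domains: DomainAssignment,
    fdr: float = 0.01,
    pool_correction: bool = False,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per domain.

    Returns a tidy table with one row per (domain, gene): the rank-sum
    z statistic, log2 fold change of means, raw and BH-adjusted p-values
    and a significance flag at the requested FDR. Adjustment is applied
    within each domain's gene list by default (``pool_correction=True``
    adjusts across all domains jointly). Domains with fewer than two spots
    are skipped with a warning.
    """
    labels = domains.labels
    if len(labels) != expr.n_spots:
        raise ValueError("domain labels must cover every spot")
    if domains.n_domains < 2:
        raise ValueError("marker testing needs at least two domains")
    x = expr.values
    rows = []
    for d in range(domains.n_domains):
        in_d = labels == d
        n_in = int(in_d.sum())
        if n_in < 2 or (~in_d).sum() < 2:
            warnings.warn(f"domain {d} has fewer than 2 spots; skipped")
            continue
        grp, rest = x[in_d], x[~in_d]
        res = stats.mannwhitneyu(grp, rest, axis=0, alternative="two-sided")
        mu = res.statistic
        n1, n2 = grp.shape[0], rest.shape[0]
        z = (mu - n1 * n2 / 2.0) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        # means are clipped at zero: log-normalized input is non-negative,
        # but reconstructions can dip slightly below
        lfc = np.log2(
            (np.maximum(grp.mean(axis=0), 0) + 1e-9)
            / (np.maximum(rest.mean(axis=0), 0) + 1e-9)
        )
        rows.append(
            pd.DataFrame(
                {
                    "domain": d,
                    "gene": expr.gene_names,
                    "score": z,
                    "log2fc": lfc,
                    "pval": res.pvalue,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    if pool_correction:
        table["pval_adj"] = multipletests(table["pval"], method="fdr_bh")[1]
    else:
        table["pval_adj"] = (
            table.groupby("domain")["pval"]
            .transform(lambda p: multipletests(p, method="fdr_bh")[1])
        )
    table["significant"] = table["pval_adj"] < fdr
    return table


def morans_i(values: np.ndarray, snn: SpatialNeighborNetwork) -> float:
    """Moran's I of a per-spot value over the SNN (self-loops excluded).

    I = (N / W) * sum_ij w_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2
    with binary weights w_ij from the adjacency minus its diagonal.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    n = snn.n_spots
    if len(v) != n:
        raise ValueError("one value per spot required")
    dev = v - v.mean()
    denom = (dev**2).sum()
    if denom == 0:
        raise ValueError("Moran's I undefined for zero-variance values")
    w = snn.adjacency.astype(float).copy()
    w.setdiag(0)
    w.eliminate_zeros()
    num = float(dev @ (w @ dev))
    return float(n / w.sum() * num / denom)


def denoised_expression(recon: ExpressionMatrix) -> ExpressionMatrix:
    """Package the decoder reconstruction as the denoised expression matrix."""
    return ExpressionMatrix(
        recon.values.copy(),
        recon.gene_names.copy(),
        recon.spot_ids.copy(),
        denoised=True,
    )


def clustering_agreement(
    labels_true: np.ndarray, labels_pred: np.ndarray
) -> dict[str, float]:
    """ARI, NMI and homogeneity against reference labels."""
    return {
        "ari": float(skmetrics.adjusted_rand_score(labels_true, labels_pred)),
        "nmi": float(
            skmetrics.normalized_mutual_info_score(labels_true, labels_pred)
        ),
        "homogeneity": float(
            skmetrics.homogeneity_score(labels_true, labels_pred)
        ),
    }
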
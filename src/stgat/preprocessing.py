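"""Counts-to-model-input preprocessing.

The model consumes library-size-normalized, log1p-transformed expression
restricted to highly variable genes (HVGs). Normalization and HVG scoring
are delegated to scanpy so the behavior matches the mainstream single-cell
ecosystem; this module owns the contracts (spot filtering, error handling,
gene ordering).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

from .datasets import ExpressionMatrix, RawDataset


def filter_spots(raw: RawDataset) -> RawDataset:
    """Drop spots flagged outside the main tissue area.

    Identity when no mask is present. Coordinates, section labels and IDs
    are subset in lockstep with the count rows.
    """
    if raw.in_tissue_mask is None:
        return raw
    keep = np.flatnonzero(raw.in_tissue_mask)
    if len(keep) == 0:
        raise ValueError("no spots remain after tissue filtering")
    out = raw.subset_spots(keep)
    out.in_tissue_mask = None
    return out


def drop_empty_spots(raw: RawDataset) -> RawDataset:
    """Remove spots whose total count is zero.

    Heavy dropout (or aggressive downsampling) can empty a spot entirely;
    such barcodes carry no expression to normalize and are discarded, as
    with empty barcodes in real runs. Identity when every spot has counts.
    """
    libsize = np.asarray(raw.counts_dense().sum(axis=1)).ravel()
    keep = np.flatnonzero(libsize > 0)
    if len(keep) == raw.n_spots:
        return raw
    if len(keep) == 0:
        raise ValueError("no spots remain after dropping empty spots")
    return raw.subset_spots(keep)


def lognormalize(
    raw: RawDataset, target_sum: Union[float, str] = "median"
) -> ExpressionMatrix:
    """Scale each spot to a common library size, then apply log(1 + x).

    ``target_sum="median"`` (default) scales to the median library size
    across spots, which is scale-free; a positive float fixes the target
    explicitly. Spots with zero total count are rejected by name.
    """
    counts = raw.counts_dense().astype(float)
    libsize = counts.sum(axis=1)
    zero = np.flatnonzero(libsize == 0)
    if len(zero):
        raise ValueError(
            f"spot(s) with zero total count cannot be normalized: "
            f"{', '.join(map(str, raw.spot_ids[zero[:5]]))}"
        )
    if target_sum == "median":
        target: Optional[float] = None  # scanpy default = median library size
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    ad = AnnData(counts)
    sc.pp.normalize_total(ad, target_sum=target)
    sc.pp.log1p(ad)
    values = ad.X if not sp.issparse(ad.X) else np.asarray(ad.X.todense())
    return ExpressionMatrix(values, raw.gene_names.copy(), raw.spot_ids.copy())


def select_hvg(expr: ExpressionMatrix, n_top: int = 3000) -> ExpressionMatrix:
    """Restrict to the ``n_top`` most variable genes.

    Variability is scored by mean-binned normalized dispersion on the
    log-normalized values (the long-standing single-cell default). Genes
    with zero variance have undefined dispersion and are never selected.
    Gene order of the output follows the input matrix; if fewer than
    ``n_top`` informative genes exist, all are kept.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    n_genes = expr.n_genes
    if n_top >= n_genes:
        return expr
    variances = expr.values.var(axis=0)
    informative = variances > 0
    if n_top >= informative.sum():
        keep = np.flatnonzero(informative)
    else:
        ad = AnnData(expr.values[:, informative])
        ad.var_names = [str(g) for g in expr.gene_names[informative]]
        sc.pp.highly_variable_genes(ad, flavor="seurat", n_top_genes=n_top)
        # rank on the binned-normalized dispersion, raw dispersion breaking
        # ties (the binning degenerates when genes are few)
        score = np.lexsort(
            (-ad.var["dispersions"].to_numpy(), -ad.var["dispersions_norm"].to_numpy())
        )[:n_top]
        chosen = set(ad.var_names[score])
        keep = np.flatnonzero(
            [str(g) in chosen for g in expr.gene_names]
        )
    return ExpressionMatrix(
        expr.values[:, keep], expr.gene_names[keep], expr.spot_ids.copy()
    )


def preprocess(
    raw: RawDataset,
    target_sum: Union[float, str] = "median",
    n_top_genes: int = 3000,
    hvg_per_section: bool = False,
) -> ExpressionMatrix:
    """filter_spots -> lognormalize -> select_hvg in one call.

    For multi-section data, HVGs are scored jointly across sections by
    default; ``hvg_per_section=True`` instead scores each section
    separately and keeps the intersection, guarding against a single
    deviant section dominating the ranking.
    """
    raw = filter_spots(raw)
    expr = lognormalize(raw, target_sum)
    if hvg_per_section and raw.sections is not None:
        sections = np.unique(raw.sections)
        kept: Optional[set] = None
        for s in sections:
            m = raw.sections == s
            sub = ExpressionMatrix(
                expr.values[m], expr.gene_names, expr.spot_ids[m]
            )
            genes = set(select_hvg(sub, n_top_genes).gene_names)
            kept = genes if kept is None else (kept & genes)
        keep = np.flatnonzero([g in kept for g in expr.gene_names])
        if len(keep) == 0:
            raise ValueError("per-section HVG intersection is empty")
        return ExpressionMatrix(
            expr.values[:, keep], expr.gene_names[keep], expr.spot_ids.copy()
        )
    return select_hvg(expr, n_top_genes)
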
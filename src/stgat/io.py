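"""Readers and writers for the formats the pipeline consumes and emits.

Supported dataset layouts:

* ``mtx+csv`` — MatrixMarket counts (spots x genes) + ``genes.tsv`` +
  ``coords.csv`` (columns ``spot_id,x,y[,section][,in_tissue]``).
* ``csv`` — a dense counts CSV (spot rows, gene columns, spot_id index)
  + the same ``coords.csv``.
* ``h5ad`` — an AnnData container with coordinates in ``obsm["spatial"]``
  and optional ``obs["section"]`` / ``obs["in_tissue"]``.

Spot order always follows the coordinate table; spot IDs are the join key.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import ExpressionMatrix, RawDataset
from .graphs import SpatialNeighborNetwork


def _coords_frame(raw: RawDataset) -> pd.DataFrame:
    df = pd.DataFrame(
        {"spot_id": raw.spot_ids, "x": raw.coords[:, 0], "y": raw.coords[:, 1]}
    )
    if raw.sections is not None:
        df["section"] = raw.sections
    if raw.in_tissue_mask is not None:
        df["in_tissue"] = raw.in_tissue_mask.astype(int)
    return df


def write_dataset(raw: RawDataset, outdir: str | Path, fmt: str = "mtx+csv") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx+csv":
        scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(raw.counts))
        pd.Series(raw.gene_names).to_csv(
            outdir / "genes.tsv", sep="\t", index=False, header=False
        )
        _coords_frame(raw).to_csv(outdir / "coords.csv", index=False)
    elif fmt == "csv":
        pd.DataFrame(
            raw.counts_dense(), index=raw.spot_ids, columns=raw.gene_names
        ).to_csv(outdir / "counts.csv", index_label="spot_id")
        _coords_frame(raw).to_csv(outdir / "coords.csv", index=False)
    elif fmt == "h5ad":
        to_anndata(raw).write_h5ad(outdir / "dataset.h5ad")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_dataset(path: str | Path, fmt: str = "mtx+csv") -> RawDataset:
    """Load a dataset; validates matrix/coordinate row agreement."""
    path = Path(path)
    if fmt == "h5ad":
        f = path if path.suffix == ".h5ad" else path / "dataset.h5ad"
        return from_anndata(ad.read_h5ad(f))
    coords = pd.read_csv(path / "coords.csv")
    if fmt == "mtx+csv":
        counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        spot_ids = coords["spot_id"].astype(str).to_numpy()
    elif fmt == "csv":
        df = pd.read_csv(path / "counts.csv", index_col="spot_id")
        counts = df.to_numpy()
        genes = df.columns.astype(str)
        spot_ids = df.index.astype(str).to_numpy()
        order = coords["spot_id"].astype(str).to_numpy()
        if sorted(order) != sorted(spot_ids):
            raise ValueError("counts.csv and coords.csv disagree on spot IDs")
        counts = counts[pd.Index(spot_ids).get_indexer(order)]
        spot_ids = order
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if counts.shape[0] != len(coords):
        raise ValueError(
            f"matrix has {counts.shape[0]} spots but coordinate table has "
            f"{len(coords)} rows"
        )
    return RawDataset(
        counts=counts,
        coords=coords[["x", "y"]].to_numpy(float),
        gene_names=np.asarray(genes, object),
        spot_ids=np.asarray(spot_ids, object),
        sections=coords["section"].to_numpy(int) if "section" in coords else None,
        in_tissue_mask=coords["in_tissue"].to_numpy(bool)
        if "in_tissue" in coords
        else None,
    )


def to_anndata(raw: RawDataset) -> ad.AnnData:
    a = ad.AnnData(
        X=sp.csr_matrix(raw.counts),
        obs=pd.DataFrame(index=pd.Index(raw.spot_ids.astype(str), name="spot_id")),
        var=pd.DataFrame(index=pd.Index(raw.gene_names.astype(str), name="gene")),
    )
    a.obsm["spatial"] = raw.coords.copy()
    if raw.sections is not None:
        a.obs["section"] = raw.sections
    if raw.in_tissue_mask is not None:
        a.obs["in_tissue"] = raw.in_tissue_mask
    return a


def from_anndata(a: ad.AnnData) -> RawDataset:
    if "spatial" not in a.obsm:
        raise ValueError('AnnData must carry coordinates in obsm["spatial"]')
    return RawDataset(
        counts=sp.csr_matrix(a.X),
        coords=np.asarray(a.obsm["spatial"], float)[:, :2],
        gene_names=a.var_names.to_numpy(object),
        spot_ids=a.obs_names.to_numpy(object),
        sections=a.obs["section"].to_numpy(int) if "section" in a.obs else None,
        in_tissue_mask=a.obs["in_tissue"].to_numpy(bool)
        if "in_tissue" in a.obs
        else None,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.spot_ids, columns=expr.gene_names).to_csv(
        path, index_label="spot_id"
    )


def read_expression(path: str | Path, denoised: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col="spot_id")
    return ExpressionMatrix(
        df.to_numpy(float),
        df.columns.to_numpy(object),
        df.index.astype(str).to_numpy(object),
        denoised=denoised,
    )


def write_snn_edges(
    snn: SpatialNeighborNetwork,
    spot_ids: np.ndarray,
    path: str | Path,
    weights: Optional[np.ndarray] = None,
) -> None:
    """Edge-list TSV (spot_id_a, spot_id_b[, weight]), self-loops included."""
    recv, neigh = snn.edge_arrays()
    df = pd.DataFrame(
        {"spot_id_a": np.asarray(spot_ids)[recv], "spot_id_b": np.asarray(spot_ids)[neigh]}
    )
    if weights is not None:
        df["weight"] = weights
    df.to_csv(path, sep="\t", index=False)


def read_snn_edges(path: str | Path, spot_ids: np.ndarray) -> SpatialNeighborNetwork:
    df = pd.read_csv(path, sep="\t")
    index = {s: i for i, s in enumerate(np.asarray(spot_ids, object))}
    rows = np.array([index[s] for s in df["spot_id_a"].astype(str)])
    cols = np.array([index[s] for s in df["spot_id_b"].astype(str)])
    n = len(spot_ids)
    a = sp.csr_matrix((np.ones(len(rows), np.int8), (rows, cols)), shape=(n, n))
    return SpatialNeighborNetwork(a.maximum(a.T))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
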
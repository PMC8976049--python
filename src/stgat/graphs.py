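"""Spatial neighbor network (SNN) construction.

An SNN is an undirected binary graph over spots with self-loops. Three
builders are provided: a radius rule (edge iff Euclidean distance < r,
strictly), a k-nearest-neighbor rule symmetrized by union (k=6 matches the
hexagonal Visium lattice), and a 3D builder that unions per-section 2D SNNs
with inter-section edges between in-plane-close spots of adjacent sections.

An optional cell type-aware variant prunes SNN edges joining spots assigned
to different expression pre-clusters (Louvain at low resolution on PCA),
sharpening domain boundaries on low-resolution platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph
import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datasets import ExpressionMatrix


@dataclass
class SpatialNeighborNetwork:
    """Sparse symmetric binary adjacency over spots, self-loops included."""

    adjacency: sp.csr_matrix
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency, dtype=np.int8)
        a.data[:] = 1
        a.setdiag(1)  # self-loops are part of the contract
        a.eliminate_zeros()
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of directed edges including self-loops."""
        return self.adjacency.nnz

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(receiver, neighbor) index arrays, one entry per directed edge.

        Edge order is deterministic (CSR row-major) and is the canonical
        ordering for per-edge attention values.
        """
        coo = self.adjacency.tocoo()
        return np.asarray(coo.row), np.asarray(coo.col)

    def neighbor_set(self, i: int) -> np.ndarray:
        """Neighbor indices S_i of spot i (includes i itself)."""
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def mean_degree(self) -> float:
        """Mean number of off-diagonal neighbors per spot."""
        return float((self.adjacency.nnz - self.n_spots) / self.n_spots)

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be (n_spots, n_dims) with n_spots >= 1")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain NaN or infinite values")
    return coords


def build_radius_snn(coords: np.ndarray, r: float) -> SpatialNeighborNetwork:
    """Edge between spots i, j iff ||coords_i - coords_j|| < r (strict)."""
    coords = _check_coords(coords)
    if r <= 0:
        raise ValueError("radius must be positive")
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    # query_pairs uses distance <= r; enforce the strict inequality
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]
    row = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.array([], int)
    col = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.array([], int)
    a = sp.csr_matrix((np.ones(len(row), np.int8), (row, col)), shape=(n, n))
    return SpatialNeighborNetwork(a, params={"mode": "radius", "radius": float(r)})


def build_knn_snn(coords: np.ndarray, k: int = 6) -> SpatialNeighborNetwork:
    """Union-symmetrized k-nearest-neighbor graph (k=6 for Visium).

    Ties at the k-th neighbor distance are broken by spot index order for
    determinism.
    """
    coords = _check_coords(coords)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    tree = cKDTree(coords)
    # k+1 because the query returns the spot itself at distance 0
    dist, idx = tree.query(coords, k=k + 1)
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        if len(neigh) < k:
            # self not returned when duplicates tie; take first k others
            order = np.argsort(np.linalg.norm(coords - coords[i], axis=1), kind="stable")
            neigh = [j for j in order if j != i][:k]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    a = sp.csr_matrix((np.ones(len(rows), np.int8), (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)  # union symmetrization
    return SpatialNeighborNetwork(a, params={"mode": "knn", "k": int(k)})


@dataclass
class PreClusterLabels:
    """Louvain pre-cluster membership used by the cell type-aware pruning."""

    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size < 1:
            raise ValueError("labels must cover at least one spot")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def precluster(
    expr: ExpressionMatrix,
    resolution: float = 0.2,
    n_pcs: int = 50,
    k_graph: int = 15,
    seed: int = 0,
) -> PreClusterLabels:
    """Louvain communities on a kNN graph of the top-``n_pcs`` PCA embedding.

    A deliberately coarse clustering (default resolution 0.2) whose only use
    is edge pruning; it is not a spatial-domain call.
    """
    x = expr.values
    n = x.shape[0]
    if n == 1:
        return PreClusterLabels(np.zeros(1, int), resolution)
    n_pcs = min(n_pcs, n - 1, x.shape[1])
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    k = min(k_graph, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    a = nn.kneighbors_graph(emb, mode="connectivity")
    a = a.maximum(a.T).tocoo()
    mask = a.row < a.col
    g = igraph.Graph(
        n=n, edges=list(zip(a.row[mask].tolist(), a.col[mask].tolist()))
    )
    state = random.getstate()
    try:
        random.seed(seed)
        part = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    return PreClusterLabels(np.asarray(part.membership, int), resolution)


def prune_to_aware_snn(
    snn: SpatialNeighborNetwork, labels: PreClusterLabels
) -> SpatialNeighborNetwork:
    """Drop SNN edges whose endpoints lie in different pre-clusters.

    Self-loops always survive; the result's edge set is a subset of the
    input's.
    """
    lab = labels.labels
    if len(lab) != snn.n_spots:
        raise ValueError("labels must cover every spot of the SNN")
    coo = snn.adjacency.tocoo()
    keep = lab[coo.row] == lab[coo.col]
    a = sp.csr_matrix(
        (np.ones(keep.sum(), np.int8), (coo.row[keep], coo.col[keep])),
        shape=snn.adjacency.shape,
    )
    return SpatialNeighborNetwork(
        a, params={**snn.params, "aware": True, "resolution": labels.resolution}
    )


def build_3d_snn(
    per_section_snns: Sequence[SpatialNeighborNetwork],
    coords: np.ndarray,
    sections: np.ndarray,
    inter_section_radius: Optional[float] = None,
) -> SpatialNeighborNetwork:
    """Stack per-section 2D SNNs and bridge adjacent sections.

    Sections must already be aligned; the bridge rule links spots of
    *adjacent* sections whose in-plane (x, y) distance is below
    ``inter_section_radius`` (default: the first section's radius, or 1.5x
    its median nearest-neighbor spacing in kNN mode). Non-adjacent sections
    are never linked directly.
    """
    coords = _check_coords(coords)
    sections_arr = np.asarray(sections, dtype=int)
    uniq = np.unique(sections_arr)
    if len(per_section_snns) != len(uniq):
        raise ValueError("one 2D SNN required per section")
    if len(uniq) == 1:
        return per_section_snns[0]
    if inter_section_radius is None:
        p = per_section_snns[0].params
        if "radius" in p:
            inter_section_radius = p["radius"]
        else:
            idx0 = np.flatnonzero(sections_arr == uniq[0])
            tree = cKDTree(coords[idx0])
            d, _ = tree.query(coords[idx0], k=2)
            inter_section_radius = 1.5 * float(np.median(d[:, 1]))
    if inter_section_radius <= 0:
        raise ValueError("inter_section_radius must be positive")

    section_index = [np.flatnonzero(sections_arr == s) for s in uniq]
    for snn_s, idx in zip(per_section_snns, section_index):
        if snn_s.n_spots != len(idx):
            raise ValueError("section SNN size does not match its spot count")

    n = coords.shape[0]
    blocks = sp.lil_matrix((n, n), dtype=np.int8)
    for snn_s, idx in zip(per_section_snns, section_index):
        blocks[np.ix_(idx, idx)] = snn_s.adjacency.todense()
    rows, cols = [], []
    for a_idx, b_idx in zip(section_index[:-1], section_index[1:]):
        tree_b = cKDTree(coords[b_idx])
        pairs = tree_b.query_ball_point(coords[a_idx], inter_section_radius)
        for ai, matches in zip(a_idx, pairs):
            for m in matches:
                bj = b_idx[m]
                if np.linalg.norm(coords[ai] - coords[bj]) < inter_section_radius:
                    rows.extend([ai, bj])
                    cols.extend([bj, ai])
    inter = sp.csr_matrix((np.ones(len(rows), np.int8), (rows, cols)), shape=(n, n))
    a = sp.csr_matrix(blocks).maximum(inter)
    return SpatialNeighborNetwork(
        a,
        params={
            "mode": "3d",
            "n_sections": len(uniq),
            "inter_section_radius": float(inter_section_radius),
        },
    )
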
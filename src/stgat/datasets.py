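"""Core in-memory containers shared by all pipeline stages.

Spots are measurement locations on a spatial transcriptomics chip; every
container keeps spot identifiers so stages join on IDs, never on position.
Coordinates are continuous floats in the chip's native units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class RawDataset:
    """Raw counts plus spot geometry, as read from disk or simulated.

    Attributes
    ----------
    counts
        Spot x gene non-negative integer counts (dense ndarray or CSR).
    coords
        Spot x 2 float in-plane coordinates.
    gene_names, spot_ids
        Unique string identifiers for columns / rows.
    sections
        Optional integer section index per spot (multi-section stacks);
        ``None`` for a single 2D section.
    in_tissue_mask
        Optional boolean per spot; ``False`` marks spots outside the main
        tissue area that :func:`stgat.preprocessing.filter_spots` drops.
    """

    counts: np.ndarray | sp.spmatrix
    coords: np.ndarray
    gene_names: np.ndarray
    spot_ids: np.ndarray
    sections: Optional[np.ndarray] = None
    in_tissue_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = _as_str_array(self.gene_names)
        self.spot_ids = _as_str_array(self.spot_ids)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots x 2"
            )
        if len(self.gene_names) != g:
            raise ValueError("gene_names length does not match count columns")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length does not match count rows")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids must be unique")
        if self.sections is not None:
            self.sections = np.asarray(self.sections, dtype=int)
            if self.sections.shape != (n,):
                raise ValueError("sections length does not match spot count")
        if self.in_tissue_mask is not None:
            self.in_tissue_mask = np.asarray(self.in_tissue_mask, dtype=bool)
            if self.in_tissue_mask.shape != (n,):
                raise ValueError("in_tissue_mask length does not match spot count")
        dense_min = self.counts.min() if not sp.issparse(self.counts) else self.counts.data.min(initial=0)
        if dense_min < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_spots(self, index: np.ndarray) -> "RawDataset":
        """Row-subset every per-spot field in lockstep."""
        index = np.asarray(index)
        return replace(
            self,
            counts=self.counts[index],
            coords=self.coords[index],
            spot_ids=self.spot_ids[index],
            sections=None if self.sections is None else self.sections[index],
            in_tissue_mask=None
            if self.in_tissue_mask is None
            else self.in_tissue_mask[index],
        )


@dataclass
class ExpressionMatrix:
    """Normalized log expression (the model input x_i) or a reconstruction.

    ``values`` is a dense spot x gene float matrix; ``denoised`` marks a
    matrix produced by the auto-encoder's decoder rather than by
    preprocessing raw counts.
    """

    values: np.ndarray
    gene_names: np.ndarray
    spot_ids: np.ndarray
    denoised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = _as_str_array(self.gene_names)
        self.spot_ids = _as_str_array(self.spot_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (spots x genes)")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one spot")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.spot_ids), len(self.gene_names)):
            raise ValueError("values shape does not match id lengths")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DomainAssignment:
    """Per-spot spatial-domain labels, contiguous integers from 0."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            # relabel to contiguous 0..k-1 preserving order of first appearance
            order = {}
            for lab in self.labels:
                if lab not in order:
                    order[lab] = len(order)
            self.labels = np.array([order[lab] for lab in self.labels], dtype=int)

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1
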
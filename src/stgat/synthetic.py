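"""Synthetic spatial transcriptomics with known ground truth.

Emulates the benchmark structure of real chips: spots on a hexagonal
lattice (Visium-like, six equidistant neighbors), a square grid, or dense
uniform-random positions (Slide-seq-like); contiguous spatial domains as
horizontal layers, concentric rings, or a cord-plus-arrow pair of thin
curved bands on a background (hippocampus-like); negative-binomial counts
with domain-specific marker programs; per-spot library-size variation; and
optional multi-section stacks with per-section multiplicative batch shifts.

Counts are drawn NB(mean m, dispersion phi) with Var = m + phi * m^2
(phi = 0 degenerates to Poisson). Marker genes of a domain have their mean
multiplied by 2**effect_size inside that domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from .datasets import RawDataset

_LATTICES = ("hex", "grid", "uniform-random")
_GEOMETRIES = ("layers", "concentric", "cord-arrow")


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give a Visium-like three-layer tissue."""

    lattice: str = "hex"
    n_spots: int = 1000
    domain_geometry: str = "layers"
    n_domains: int = 3
    n_genes: int = 200
    n_marker_genes: int = 50
    effect_size: float = 2.0  # log2 fold change of markers inside their domain
    nb_dispersion: float = 0.5  # phi in Var = m + phi m^2
    base_mean: float = 0.1  # per-gene baseline mean scale; ~85% zero counts, Visium-like depth
    library_size_range: tuple[float, float] = (0.5, 2.0)
    n_sections: int = 1
    batch_shift_sd: float = 0.0  # sd of per-section log-normal gene factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice not in _LATTICES:
            raise ValueError(f"lattice must be one of {_LATTICES}")
        if self.domain_geometry not in _GEOMETRIES:
            raise ValueError(f"domain_geometry must be one of {_GEOMETRIES}")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.domain_geometry == "cord-arrow" and self.n_domains != 3:
            raise ValueError("cord-arrow geometry defines exactly 3 domains")
        if self.n_domains * self.n_marker_genes > self.n_genes:
            raise ValueError("not enough genes for the requested marker programs")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must satisfy 0 < low <= high")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")


def _lattice_coords(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_spots
    if spec.lattice == "uniform-random":
        side = np.sqrt(n)
        return rng.uniform(0, side, size=(n, 2))
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    rows = np.repeat(np.arange(nrows), ncols)[:n]
    cols = np.tile(np.arange(ncols), nrows)[:n]
    x = cols.astype(float)
    y = rows.astype(float)
    if spec.lattice == "hex":
        # offset odd rows by half a spacing, compress row pitch to sqrt(3)/2:
        # every interior spot then has exactly 6 equidistant neighbors
        x = x + 0.5 * (rows % 2)
        y = y * (np.sqrt(3) / 2.0)
    return np.column_stack([x, y])


def _assign_domains(
    coords: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    if spec.domain_geometry == "layers":
        qs = np.quantile(y, np.linspace(0, 1, spec.n_domains + 1)[1:-1])
        return np.searchsorted(qs, y, side="right")
    if spec.domain_geometry == "concentric":
        r = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        qs = np.quantile(r, np.linspace(0, 1, spec.n_domains + 1)[1:-1])
        return np.searchsorted(qs, r, side="right")
    # cord-arrow: thin arc (cord) + V-shaped band (arrow) on background
    cx, cy = coords.mean(axis=0)
    span = max(x.max() - x.min(), y.max() - y.min())
    rad = np.linalg.norm(coords - [cx, cy], axis=1)
    labels = np.zeros(len(coords), dtype=int)
    arc = (np.abs(rad - 0.35 * span) < 0.05 * span) & (y > cy)
    v_dist = np.abs(np.abs(x - cx) - 0.6 * (cy - y))
    arrow = (v_dist < 0.06 * span) & (y < cy)
    labels[arc] = 1
    labels[arrow] = 2
    return labels


def marker_gene_names(spec: SyntheticSpec) -> dict[int, list[str]]:
    """Gene names of each domain's marker program."""
    return {
        d: [
            f"g{(i + 1):04d}"
            for i in range(d * spec.n_marker_genes, (d + 1) * spec.n_marker_genes)
        ]
        for d in range(spec.n_domains)
    }


def generate(spec: SyntheticSpec) -> tuple[RawDataset, np.ndarray]:
    """Sample a dataset and its ground-truth domain labels.

    Multi-section mode replicates the lattice and domain geometry per
    section, draws an independent per-section log-normal gene factor
    (sd ``batch_shift_sd``) multiplying all means, and labels every spot
    with its section index. Bit-reproducible for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    coords1 = _lattice_coords(spec, rng)
    labels1 = _assign_domains(coords1, spec, rng)
    # baseline means must be shared across sections: draw them once
    g = spec.n_genes
    all_counts, all_coords, all_labels, all_sections, all_ids = [], [], [], [], []
    # reuse one rng stream; the base means are redrawn identically per
    # section by seeding a dedicated generator
    base_rng = np.random.default_rng(spec.seed + 1)
    base = base_rng.lognormal(mean=np.log(spec.base_mean), sigma=0.4, size=g)
    fold = np.ones((spec.n_domains, g))
    for d in range(spec.n_domains):
        sl = slice(d * spec.n_marker_genes, (d + 1) * spec.n_marker_genes)
        fold[d, sl] = 2.0**spec.effect_size
    lo, hi = spec.library_size_range
    for s in range(spec.n_sections):
        section_factor = (
            np.exp(rng.normal(0.0, spec.batch_shift_sd, size=g))
            if spec.batch_shift_sd > 0
            else np.ones(g)
        )
        n = spec.n_spots
        lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        mean = base[None, :] * fold[labels1] * lib[:, None] * section_factor[None, :]
        if spec.nb_dispersion == 0:
            counts = rng.poisson(mean)
        else:
            r = 1.0 / spec.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mean))
        all_counts.append(counts)
        all_coords.append(coords1)
        all_labels.append(labels1)
        all_sections.append(np.full(n, s))
        all_ids.extend(f"s{s}_spot{i:05d}" for i in range(n))
    counts = np.vstack(all_counts)
    raw = RawDataset(
        counts=counts,
        coords=np.vstack(all_coords),
        gene_names=np.array([f"g{(i + 1):04d}" for i in range(g)], object),
        spot_ids=np.array(all_ids, object),
        sections=np.concatenate(all_sections) if spec.n_sections > 1 else None,
    )
    return raw, np.concatenate(all_labels)


def corrupt_dropout(
    raw: RawDataset, rate: float, mode: str = "zero", seed: int = 0
) -> RawDataset:
    """Thin the counts to mimic capture dropout.

    ``mode="zero"``: each nonzero entry is zeroed independently with
    probability ``rate``. ``mode="thin"``: binomial thinning, each count
    becomes Binomial(count, 1 - rate). Totals never increase.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    counts = raw.counts_dense().copy()
    if rate > 0:
        if mode == "zero":
            nz = counts > 0
            drop = rng.random(counts.shape) < rate
            counts[nz & drop] = 0
        elif mode == "thin":
            counts = rng.binomial(counts.astype(int), 1.0 - rate)
        else:
            raise ValueError("mode must be 'zero' or 'thin'")
    return replace(raw, counts=counts)
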
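import numpy as np
import pytest

import stgat
from stgat.datasets import ExpressionMatrix, RawDataset


@pytest.fixture(scope="session")
def small_raw():
    """A 100-spot hex tissue with 3 layers, deterministic."""
    spec = stgat.SyntheticSpec(
        n_spots=100, n_genes=40, n_marker_genes=10, base_mean=1.0, seed=11
    )
    raw, labels = stgat.generate(spec)
    return raw, labels


@pytest.fixture(scope="session")
def small_expr(small_raw):
    raw, _ = small_raw
    return stgat.preprocess(raw, n_top_genes=40)


@pytest.fixture(scope="session")
def small_snn(small_raw):
    raw, _ = small_raw
    return stgat.build_knn_snn(raw.coords, 6)


def random_instance(rng, n_spots, n_genes, radius=1.5):
    """A random coordinate/expression instance for fuzz tests."""
    coords = rng.uniform(0, np.sqrt(n_spots), size=(n_spots, 2))
    values = rng.normal(size=(n_spots, n_genes))
    expr = ExpressionMatrix(
        values,
        np.array([f"g{i}" for i in range(n_genes)], object),
        np.array([f"s{i}" for i in range(n_spots)], object),
    )
    return coords, expr


def make_raw(counts, coords=None, **kwargs):
    counts = np.asarray(counts)
    n, g = counts.shape
    if coords is None:
        coords = np.column_stack([np.arange(n), np.zeros(n)])
    return RawDataset(
        counts=counts,
        coords=coords,
        gene_names=np.array([f"g{i}" for i in range(g)], object),
        spot_ids=np.array([f"s{i}" for i in range(n)], object),
        **kwargs,
    )
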
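"""End-to-end workflow: preprocess -> graph -> train -> cluster -> markers.

`run_pipeline` drives the whole analysis from a single `RunConfig` and
writes every artifact (embeddings, denoised matrix, domain labels, marker
table, attention edges, loss history) plus a provenance JSON carrying the
seed, the full configuration and a config hash, so a run can be verified
as reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, downstream, graphs, io, model, preprocessing
from .datasets import RawDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter in one place.

    Defaults match the method's reference settings: k=6 spatial neighbors
    for hexagonal chips, 3000 HVGs, 512-30 layers, Adam lr 1e-4 / weight
    decay 1e-4, 500 iterations (1000 with the cell type-aware module),
    blend alpha 0.5, pre-cluster resolution 0.2.
    """

    # input
    input_path: Optional[str] = None
    input_format: str = "mtx+csv"
    # preprocessing
    target_sum: float | str = "median"
    n_top_genes: int = 3000
    hvg_per_section: bool = False
    # graph
    graph_mode: str = "knn"  # "knn" | "radius"
    k_neighbors: int = 6
    radius: Optional[float] = None
    aware: bool = False
    precluster_resolution: float = 0.2
    inter_section_radius: Optional[float] = None
    # model
    hidden_dims: tuple[int, ...] = (512, 30)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    n_iterations: Optional[int] = None
    alpha: float = 0.5
    loss: str = "squared"
    # clustering
    n_domains: Optional[int] = None  # GMM when known, Louvain otherwise
    louvain_resolution: float = 1.0
    # markers
    fdr: float = 0.01
    # run
    seed: int = 0
    out_dir: str = "stgat_run"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_graph(raw: RawDataset, config: RunConfig) -> graphs.SpatialNeighborNetwork:
    """Per-config SNN; multi-section data routes through the 3D builder."""

    def build_2d(coords: np.ndarray) -> graphs.SpatialNeighborNetwork:
        if config.graph_mode == "radius":
            if config.radius is None:
                raise ValueError("radius mode requires a radius")
            return graphs.build_radius_snn(coords, config.radius)
        return graphs.build_knn_snn(coords, config.k_neighbors)

    if raw.sections is None or len(np.unique(raw.sections)) == 1:
        return build_2d(raw.coords)
    uniq = np.unique(raw.sections)
    per_section = [build_2d(raw.coords[raw.sections == s]) for s in uniq]
    return graphs.build_3d_snn(
        per_section, raw.coords, raw.sections, config.inter_section_radius
    )


def run_pipeline(config: RunConfig, raw: Optional[RawDataset] = None) -> dict:
    """Execute the full workflow and write artifacts under ``config.out_dir``.

    ``raw`` may be passed directly (e.g. fresh from the synthetic
    generator); otherwise it is read from ``config.input_path``. Returns a
    dict of the in-memory results keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    if raw is None:
        if config.input_path is None:
            raise ValueError("either raw data or input_path is required")
        raw = stage("read", io.read_dataset, config.input_path, config.input_format)

    expr = stage(
        "preprocess",
        preprocessing.preprocess,
        raw,
        config.target_sum,
        config.n_top_genes,
        config.hvg_per_section,
    )
    raw = stage("filter_spots", preprocessing.filter_spots, raw)
    snn = stage("graph", build_graph, raw, config)
    logger.debug("graph: mean neighbors %.2f", snn.mean_degree())
    aware_snn = None
    if config.aware:
        labels = stage(
            "precluster",
            graphs.precluster,
            expr,
            config.precluster_resolution,
            seed=config.seed,
        )
        aware_snn = stage("prune", graphs.prune_to_aware_snn, snn, labels)

    tconf = model.TrainingConfig(
        hidden_dims=config.hidden_dims,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        n_iterations=config.n_iterations,
        seed=config.seed,
        alpha=config.alpha,
        loss=config.loss,
    )
    result = stage("train", model.train, expr, snn, aware_snn, tconf)

    if config.n_domains is not None:
        domains = stage(
            "cluster", downstream.cluster_gmm, result.embeddings, config.n_domains,
            config.seed,
        )
    else:
        domains = stage(
            "cluster",
            downstream.cluster_louvain,
            result.embeddings,
            config.louvain_resolution,
            seed=config.seed,
        )
    markers = None
    if domains.n_domains >= 2:
        markers = stage("markers", downstream.rank_markers, expr, domains, config.fdr)

    # artifacts
    io.write_expression(result.embeddings, out / "embeddings.csv")
    io.write_expression(result.reconstruction, out / "denoised.csv")
    pd.DataFrame(
        {"spot_id": expr.spot_ids, "domain": domains.labels}
    ).to_csv(out / "domains.csv", index=False)
    if markers is not None:
        markers.to_csv(out / "markers.csv", index=False)
    io.write_snn_edges(
        snn, expr.spot_ids, out / "attention_edges.tsv",
        weights=result.attention.layers[0],
    )
    np.savetxt(out / "loss_history.txt", result.loss_history)
    io.write_json(
        {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "version": __version__,
            "n_spots": expr.n_spots,
            "n_genes": expr.n_genes,
            "final_loss": float(result.loss_history[-1]),
        },
        out / "provenance.json",
    )
    return {
        "expression": expr,
        "snn": snn,
        "aware_snn": aware_snn,
        "train": result,
        "domains": domains,
        "markers": markers,
    }
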
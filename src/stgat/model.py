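"""Graph attention auto-encoder over a spatial neighbor network.

The encoder turns normalized expression x_i into a low-dimensional spot
embedding by aggregating over the spot's spatial neighbors S_i with learned
per-edge attention; the decoder mirrors the encoder with tied weights
(decoder weight = encoder weight transpose, decoder attention = encoder
attention) and reconstructs the expression. Training minimizes the
reconstruction error of the normalized expression by full-batch Adam.

Layer structure (default dims input -> 512 -> 30):

* encoder layer k < L:  h_i^(k) = sigma( sum_{j in S_i} att_ij^(k) W_k h_j^(k-1) )
* encoder layer L:      h_i^(L) = sigma( W_L h_i^(L-1) )           (no attention)
* decoder layer k > 1:  mirrored aggregation with W_k^T and att^(k-1)
* decoder layer 1:      xhat_i = sigma( W_1^T hhat_i^(1) )          (no attention)

Per-edge raw scores e_ij = Sigmoid(v_s^T (W_k h_i) + v_r^T (W_k h_j)) are
softmax-normalized over each receiving spot's neighbor set (self-loop
included), so every spot's incoming attention sums to one.

With the cell type-aware module, attention is additionally normalized over
the pruned neighbor sets and the two maps are blended:
att = (1 - alpha) * att_spatial + alpha * att_aware, with att_aware zero on
pruned-away edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import _autograd as ag
from .datasets import ExpressionMatrix
from .graphs import SpatialNeighborNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "TrainingConfig",
    "AttentionMap",
    "TrainResult",
    "attention_scores",
    "normalize_attention",
    "blend_attention",
    "encode",
    "decode",
    "forward",
    "reconstruction_loss",
    "train",
]


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ModelParams:
    """Encoder parameters; the decoder is derived, never stored.

    ``weights[k]`` has shape (dims[k], dims[k+1]); attention vectors exist
    for every layer but the last. Decoder weights are the transposes of the
    encoder weights (``decoder_weights`` materializes them) and the decoder
    reuses the encoder's attention maps, so the parameter count is that of
    the encoder alone.
    """

    dims: Sequence[int]
    weights: list[np.ndarray]
    att_v_self: list[np.ndarray]
    att_v_neigh: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def decoder_weights(self) -> list[np.ndarray]:
        """Materialized tied decoder weights, W_k transposed."""
        return [w.T for w in self.weights]

    @classmethod
    def initialize(
        cls, dims: Sequence[int], rng: np.random.Generator
    ) -> "ModelParams":
        """Glorot-uniform initialization for weights and attention vectors."""
        weights, v_self, v_neigh = [], [], []
        n_layers = len(dims) - 1
        for k in range(n_layers):
            fan_in, fan_out = dims[k], dims[k + 1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            if k < n_layers - 1:
                lim_v = np.sqrt(6.0 / (fan_out + 1))
                v_self.append(rng.uniform(-lim_v, lim_v, size=fan_out))
                v_neigh.append(rng.uniform(-lim_v, lim_v, size=fan_out))
        return cls(list(dims), weights, v_self, v_neigh)


@dataclass
class TrainingConfig:
    """Hyperparameters of the full-batch training loop.

    ``n_iterations=None`` resolves to 500, or 1000 when the cell type-aware
    module is active. ``alpha`` is the blend weight of the aware attention.
    ``loss`` selects the squared per-spot norm (default, smooth at zero) or
    the plain (un-squared) norm.
    """

    hidden_dims: Sequence[int] = (512, 30)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    n_iterations: Optional[int] = None
    seed: int = 0
    alpha: float = 0.5
    loss: str = "squared"

    def resolved_iterations(self, aware: bool) -> int:
        if self.n_iterations is not None:
            if self.n_iterations < 1:
                raise ValueError("n_iterations must be >= 1")
            return self.n_iterations
        return 1000 if aware else 500


@dataclass
class AttentionMap:
    """Normalized per-edge attention on the SNN's canonical edge order."""

    receivers: np.ndarray
    neighbors: np.ndarray
    layers: list[np.ndarray]
    spatial_layers: Optional[list[np.ndarray]] = None
    aware_layers: Optional[list[np.ndarray]] = None
    alpha: Optional[float] = None

    def dense(self, layer: int, n: int) -> sp.csr_matrix:
        """Sparse matrix M with M[i, j] = att_ij for the given layer."""
        return sp.csr_matrix(
            (self.layers[layer], (self.receivers, self.neighbors)), shape=(n, n)
        )


@dataclass
class TrainResult:
    params: ModelParams
    embeddings: ExpressionMatrix
    reconstruction: ExpressionMatrix
    attention: AttentionMap
    loss_history: np.ndarray


# ---------------------------------------------------------------------------
# Functional forward path (plain NumPy; mirrored by the autodiff tape below)
# ---------------------------------------------------------------------------


def attention_scores(
    h: np.ndarray,
    weight: np.ndarray,
    v_self: np.ndarray,
    v_neigh: np.ndarray,
    snn: SpatialNeighborNetwork,
) -> np.ndarray:
    """Raw edge scores e_ij = Sigmoid(v_s . W h_i + v_r . W h_j).

    Returned in the SNN's canonical edge order; i is the receiving spot,
    j the neighbor (self-loops included). Scores lie in (0, 1).
    """
    if h.shape[1] != weight.shape[0]:
        raise ValueError(
            f"feature dim {h.shape[1]} does not match weight rows {weight.shape[0]}"
        )
    z = h @ weight
    if z.shape[1] != len(v_self) or z.shape[1] != len(v_neigh):
        raise ValueError("attention vector length does not match layer width")
    recv, neigh = snn.edge_arrays()
    f_self = z @ v_self
    f_neigh = z @ v_neigh
    return _sigmoid(f_self[recv] + f_neigh[neigh])


def normalize_attention(
    e: np.ndarray, snn: SpatialNeighborNetwork
) -> np.ndarray:
    """Softmax of raw scores over each receiving spot's neighbor set."""
    recv, _ = snn.edge_arrays()
    if len(e) != len(recv):
        raise ValueError("one raw score per SNN edge required")
    ex = np.exp(e)
    denom = np.zeros(snn.n_spots)
    np.add.at(denom, recv, ex)
    return ex / denom[recv]


def _aware_edge_positions(
    snn: SpatialNeighborNetwork, aware_snn: SpatialNeighborNetwork
) -> np.ndarray:
    """Positions of the pruned SNN's edges inside the full SNN edge order."""
    recv, neigh = snn.edge_arrays()
    recv_a, neigh_a = aware_snn.edge_arrays()
    n = snn.n_spots
    full_lin = recv.astype(np.int64) * n + neigh
    aware_lin = recv_a.astype(np.int64) * n + neigh_a
    pos = np.searchsorted(full_lin, aware_lin)
    if np.any(pos >= len(full_lin)) or np.any(full_lin[pos] != aware_lin):
        raise ValueError("aware SNN edges are not a subset of the SNN edges")
    return pos


def blend_attention(
    att_spatial: np.ndarray,
    att_aware: np.ndarray,
    alpha: float = 0.5,
    snn: Optional[SpatialNeighborNetwork] = None,
    aware_snn: Optional[SpatialNeighborNetwork] = None,
) -> np.ndarray:
    """att = (1 - alpha) * att_spatial + alpha * att_aware.

    ``att_aware`` lives on the pruned edge set and counts as zero on
    pruned-away edges; pass both networks so the aware values can be
    embedded into the full edge order (not needed when the edge sets
    coincide).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if len(att_aware) == len(att_spatial):
        expanded = att_aware
    else:
        if snn is None or aware_snn is None:
            raise ValueError(
                "snn and aware_snn are required when edge sets differ"
            )
        expanded = np.zeros_like(att_spatial)
        expanded[_aware_edge_positions(snn, aware_snn)] = att_aware
    return (1.0 - alpha) * att_spatial + alpha * expanded


def _check_finite(h: np.ndarray, what: str) -> np.ndarray:
    if not np.all(np.isfinite(h)):
        raise FloatingPointError(f"non-finite values in {what} (training diverged?)")
    return h


def encode(
    x: np.ndarray,
    params: ModelParams,
    atts: Sequence[np.ndarray],
    snn: SpatialNeighborNetwork,
    activation: Callable[[np.ndarray], np.ndarray] = _elu,
) -> np.ndarray:
    """Run the encoder; ``atts[k]`` is the normalized attention of layer k+1."""
    recv, neigh = snn.edge_arrays()
    h = np.asarray(x, dtype=float)
    n_layers = params.n_layers
    if len(atts) != n_layers - 1:
        raise ValueError("one attention map per attention-bearing layer required")
    for k in range(n_layers - 1):
        z = h @ params.weights[k]
        msg = z[neigh] * atts[k][:, None]
        agg = np.zeros_like(z)
        np.add.at(agg, recv, msg)
        h = _check_finite(activation(agg), f"encoder layer {k + 1}")
    h = activation(h @ params.weights[-1])
    return _check_finite(h, "encoder output")


def decode(
    h: np.ndarray,
    params: ModelParams,
    atts: Sequence[np.ndarray],
    snn: SpatialNeighborNetwork,
    activation: Callable[[np.ndarray], np.ndarray] = _elu,
) -> np.ndarray:
    """Mirror of :func:`encode` with transposed weights and reused attention."""
    recv, neigh = snn.edge_arrays()
    n_layers = params.n_layers
    if len(atts) != n_layers - 1:
        raise ValueError("one attention map per attention-bearing layer required")
    out = np.asarray(h, dtype=float)
    for k in range(n_layers - 1, 0, -1):
        z = out @ params.weights[k].T
        msg = z[neigh] * atts[k - 1][:, None]
        agg = np.zeros_like(z)
        np.add.at(agg, recv, msg)
        out = _check_finite(activation(agg), f"decoder layer {k}")
    out = activation(out @ params.weights[0].T)
    return _check_finite(out, "decoder output")


def forward(
    x: np.ndarray,
    params: ModelParams,
    snn: SpatialNeighborNetwork,
    aware_snn: Optional[SpatialNeighborNetwork] = None,
    alpha: float = 0.5,
    activation: Callable[[np.ndarray], np.ndarray] = _elu,
) -> tuple[np.ndarray, np.ndarray, AttentionMap]:
    """Full forward pass: (embeddings, reconstruction, attention)."""
    recv, neigh = snn.edge_arrays()
    h = np.asarray(x, dtype=float)
    atts, att_sp, att_aw = [], [], []
    for k in range(params.n_layers - 1):
        e = attention_scores(
            h, params.weights[k], params.att_v_self[k], params.att_v_neigh[k], snn
        )
        a_sp = normalize_attention(e, snn)
        if aware_snn is not None:
            pos = _aware_edge_positions(snn, aware_snn)
            e_aw = e[pos]
            a_aw = normalize_attention(e_aw, aware_snn)
            a = blend_attention(a_sp, a_aw, alpha, snn=snn, aware_snn=aware_snn)
            att_aw.append(a_aw)
        else:
            a = a_sp
        att_sp.append(a_sp)
        atts.append(a)
        z = h @ params.weights[k]
        msg = z[neigh] * a[:, None]
        agg = np.zeros_like(z)
        np.add.at(agg, recv, msg)
        h = activation(agg)
    emb = activation(h @ params.weights[-1])
    recon = decode(emb, params, atts, snn, activation)
    attmap = AttentionMap(
        recv,
        neigh,
        atts,
        spatial_layers=att_sp,
        aware_layers=att_aw if aware_snn is not None else None,
        alpha=alpha if aware_snn is not None else None,
    )
    return emb, recon, attmap


def reconstruction_loss(
    x: np.ndarray, x_hat: np.ndarray, mode: str = "squared"
) -> float:
    """Sum over spots of the (squared) Euclidean reconstruction error."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    sq = ((x - x_hat) ** 2).sum(axis=-1)
    if mode == "squared":
        return float(sq.sum())
    if mode == "norm":
        return float(np.sqrt(sq).sum())
    raise ValueError("loss mode must be 'squared' or 'norm'")


# ---------------------------------------------------------------------------
# Training (autodiff tape)
# ---------------------------------------------------------------------------


@dataclass
class _EdgeOps:
    """Constant sparse operators for gather/scatter on an edge set."""

    recv: np.ndarray
    neigh: np.ndarray
    gather_recv: sp.csr_matrix  # (E, N) selects receiver rows
    gather_neigh: sp.csr_matrix  # (E, N) selects neighbor rows
    scatter_recv: sp.csr_matrix  # (N, E) sums per-edge values into receivers
    scatter_neigh: sp.csr_matrix  # (N, E) transpose of gather_neigh
    template: sp.csr_matrix  # (N, N) edge-set sparsity in canonical order

    @classmethod
    def build(cls, recv: np.ndarray, neigh: np.ndarray, n: int) -> "_EdgeOps":
        e = len(recv)
        ones = np.ones(e)
        g_recv = sp.csr_matrix((ones, (np.arange(e), recv)), shape=(e, n))
        g_neigh = sp.csr_matrix((ones, (np.arange(e), neigh)), shape=(e, n))
        template = sp.csr_matrix((np.ones(e), (recv, neigh)), shape=(n, n))
        assert np.array_equal(template.tocoo().row, recv)
        return cls(
            recv, neigh, g_recv, g_neigh,
            g_recv.T.tocsr(), g_neigh.T.tocsr(), template,
        )


def _tape_attention(
    z: ag.Tensor, v_self: ag.Tensor, v_neigh: ag.Tensor, ops: _EdgeOps
) -> tuple[ag.Tensor, ag.Tensor]:
    """(raw scores e, normalized att) on the tape; both shaped (E, 1)."""
    f_self = ag.matmul(z, v_self)
    f_neigh = ag.matmul(z, v_neigh)
    e = ag.sigmoid(
        ag.add(
            ag.smm(ops.gather_recv, f_self, ops.scatter_recv),
            ag.smm(ops.gather_neigh, f_neigh, ops.scatter_neigh),
        )
    )
    ex = ag.exp(e)
    denom = ag.smm(
        ops.gather_recv,
        ag.smm(ops.scatter_recv, ex, ops.gather_recv),
        ops.scatter_recv,
    )
    return e, ag.div(ex, denom)


def _tape_forward(
    x: ag.Tensor,
    weights: list[ag.Tensor],
    v_self: list[ag.Tensor],
    v_neigh: list[ag.Tensor],
    ops: _EdgeOps,
    aware: Optional[tuple[_EdgeOps, sp.csr_matrix, sp.csr_matrix]],
    alpha: float,
    loss_mode: str,
) -> tuple[ag.Tensor, ag.Tensor, ag.Tensor, list[ag.Tensor]]:
    """Build the loss tape; returns (loss, embedding, reconstruction, atts)."""
    n_layers = len(weights)
    h = x
    atts: list[ag.Tensor] = []
    for k in range(n_layers - 1):
        z = ag.matmul(h, weights[k])
        e, a_sp = _tape_attention(z, v_self[k], v_neigh[k], ops)
        if aware is not None:
            aware_ops, embed, embed_t = aware
            e_aw = ag.smm(embed_t, e, embed)
            ex = ag.exp(e_aw)
            denom = ag.smm(
                aware_ops.gather_recv,
                ag.smm(aware_ops.scatter_recv, ex, aware_ops.gather_recv),
                aware_ops.scatter_recv,
            )
            a_aw = ag.div(ex, denom)
            a = ag.add(
                ag.scale(a_sp, 1.0 - alpha),
                ag.scale(ag.smm(embed, a_aw, embed_t), alpha),
            )
        else:
            a = a_sp
        atts.append(a)
        h = ag.elu(ag.attn_aggregate(z, a, ops.recv, ops.neigh, ops.template))
    emb = ag.elu(ag.matmul(h, weights[-1]))
    # decoder: tied weights, reused attention
    out = emb
    for k in range(n_layers - 1, 0, -1):
        z = ag.matmul_t(out, weights[k])
        out = ag.elu(
            ag.attn_aggregate(z, atts[k - 1], ops.recv, ops.neigh, ops.template)
        )
    recon = ag.elu(ag.matmul_t(out, weights[0]))
    diff = ag.sub(x, recon)
    if loss_mode == "squared":
        loss = ag.sum_all(ag.square(diff))
    elif loss_mode == "norm":
        loss = ag.sum_all(ag.row_norms(diff))
    else:
        raise ValueError("loss mode must be 'squared' or 'norm'")
    return loss, emb, recon, atts


def train(
    expr: ExpressionMatrix,
    snn: SpatialNeighborNetwork,
    aware_snn: Optional[SpatialNeighborNetwork] = None,
    config: Optional[TrainingConfig] = None,
    callback: Optional[Callable[[int, float, AttentionMap], None]] = None,
) -> TrainResult:
    """Train the auto-encoder by full-batch Adam on the whole graph.

    Attention is recomputed from the current parameters at every iteration
    and gradients flow through it. ``callback(iteration, loss, attention)``
    runs after each optimizer step (attention as of the step's forward
    pass), useful for monitoring.

    Returns the final parameters, spot embeddings (for clustering),
    reconstruction (for denoising), last-iteration attention and the loss
    history.
    """
    config = config or TrainingConfig()
    if expr.n_spots != snn.n_spots:
        raise ValueError("expression matrix and SNN disagree on spot count")
    if not 0.0 <= config.alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n_iter = config.resolved_iterations(aware_snn is not None)
    dims = [expr.n_genes, *config.hidden_dims]
    rng = np.random.default_rng(config.seed)
    params = ModelParams.initialize(dims, rng)

    recv, neigh = snn.edge_arrays()
    ops = _EdgeOps.build(recv, neigh, snn.n_spots)
    aware = None
    if aware_snn is not None:
        pos = _aware_edge_positions(snn, aware_snn)
        recv_a, neigh_a = aware_snn.edge_arrays()
        aware_ops = _EdgeOps.build(recv_a, neigh_a, snn.n_spots)
        embed = sp.csr_matrix(
            (np.ones(len(pos)), (pos, np.arange(len(pos)))),
            shape=(len(recv), len(pos)),
        )
        aware = (aware_ops, embed, embed.T.tocsr())

    w_t = [ag.param(w) for w in params.weights]
    vs_t = [ag.param(v.reshape(-1, 1)) for v in params.att_v_self]
    vr_t = [ag.param(v.reshape(-1, 1)) for v in params.att_v_neigh]
    all_params = [*w_t, *vs_t, *vr_t]
    opt = ag.Adam(
        all_params, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    x_const = ag.const(expr.values)
    losses = np.empty(n_iter)
    for it in range(n_iter):
        opt.zero_grad()
        loss, _, _, atts = _tape_forward(
            x_const, w_t, vs_t, vr_t, ops, aware, config.alpha, config.loss
        )
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite reconstruction loss at iteration {it}"
            )
        loss.backward()
        opt.step()
        losses[it] = loss_val
        if it % 50 == 0 or it == n_iter - 1:
            logger.info("iteration %d: loss %.4f", it, loss_val)
        if callback is not None:
            attmap = AttentionMap(
                recv, neigh, [a.data.reshape(-1).copy() for a in atts]
            )
            callback(it, loss_val, attmap)

    params = ModelParams(
        dims,
        [w.data for w in w_t],
        [v.data.reshape(-1) for v in vs_t],
        [v.data.reshape(-1) for v in vr_t],
    )
    emb, recon, attmap = forward(
        expr.values, params, snn, aware_snn, config.alpha
    )
    return TrainResult(
        params=params,
        embeddings=ExpressionMatrix(
            emb,
            np.array([f"dim_{i}" for i in range(emb.shape[1])], object),
            expr.spot_ids.copy(),
        ),
        reconstruction=ExpressionMatrix(
            recon, expr.gene_names.copy(), expr.spot_ids.copy(), denoised=True
        ),
        attention=attmap,
        loss_history=losses,
    )
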
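"""Auto-encoder unit tests against hand arithmetic and a dense oracle.

The dense oracle materializes the full N x N attention matrix and runs the
layer algebra with plain dense products — an independent re-derivation of
the sparse edge-wise path.
"""

import numpy as np
import pytest
import scipy.sparse as sp

import stgat
from stgat.datasets import ExpressionMatrix
from stgat.graphs import SpatialNeighborNetwork, build_radius_snn
from stgat.model import (
    ModelParams,
    TrainingConfig,
    attention_scores,
    blend_attention,
    decode,
    encode,
    forward,
    normalize_attention,
    reconstruction_loss,
    train,
)


def snn_from_dense(a):
    return SpatialNeighborNetwork(sp.csr_matrix(np.asarray(a)))


def random_snn(rng, n, p=0.3):
    a = rng.random((n, n)) < p
    return snn_from_dense(np.triu(a, 1) | np.triu(a, 1).T | np.eye(n, dtype=bool))


def dense_oracle(x, params, snn, alpha=None, aware_snn=None):
    """Dense re-implementation: explicit attention matrices, no sparsity."""
    a_mask = snn.adjacency.toarray().astype(bool)
    h = np.asarray(x, float)
    elu = lambda v: np.where(v > 0, v, np.expm1(np.minimum(v, 0)))
    sig = lambda v: 1 / (1 + np.exp(-v))
    att_mats = []
    n_layers = params.n_layers
    for k in range(n_layers - 1):
        z = h @ params.weights[k]
        e = sig(
            (z @ params.att_v_self[k])[:, None] + (z @ params.att_v_neigh[k])[None, :]
        )
        ex = np.where(a_mask, np.exp(e), 0.0)
        att = ex / ex.sum(axis=1, keepdims=True)
        if aware_snn is not None:
            mask_aw = aware_snn.adjacency.toarray().astype(bool)
            ex_aw = np.where(mask_aw, np.exp(e), 0.0)
            att_aw = ex_aw / ex_aw.sum(axis=1, keepdims=True)
            att = (1 - alpha) * att + alpha * att_aw
        att_mats.append(att)
        h = elu(att @ z)
    emb = elu(h @ params.weights[-1])
    out = emb
    for k in range(n_layers - 1, 0, -1):
        out = elu(att_mats[k - 1] @ (out @ params.weights[k].T))
    recon = elu(out @ params.weights[0].T)
    return emb, recon


class TestAttentionScores:
    def test_zero_vectors_give_half(self):
        snn = random_snn(np.random.default_rng(0), 5)
        h = np.random.default_rng(1).normal(size=(5, 3))
        w = np.random.default_rng(2).normal(size=(3, 4))
        e = attention_scores(h, w, np.zeros(4), np.zeros(4), snn)
        np.testing.assert_allclose(e, 0.5)

    def test_scalar_hand_case(self):
        # W=1, v_s=0.5, v_r=0.25, h_i=1, h_j=2 -> Sigmoid(0.5 + 0.5) = Sigmoid(1)
        snn = snn_from_dense([[1, 1], [1, 1]])
        e = attention_scores(
            np.array([[1.0], [2.0]]),
            np.array([[1.0]]),
            np.array([0.5]),
            np.array([0.25]),
            snn,
        )
        recv, neigh = snn.edge_arrays()
        k = np.flatnonzero((recv == 0) & (neigh == 1))[0]
        np.testing.assert_allclose(e[k], 1 / (1 + np.exp(-1.0)))
        assert np.all((e > 0) & (e < 1))

    def test_symmetric_when_vectors_equal(self):
        rng = np.random.default_rng(3)
        snn = random_snn(rng, 8)
        h = rng.normal(size=(8, 4))
        w = rng.normal(size=(4, 5))
        v = rng.normal(size=5)
        e = attention_scores(h, w, v, v, snn)
        m = sp.csr_matrix((e, snn.edge_arrays()), shape=(8, 8)).toarray()
        np.testing.assert_allclose(m, m.T)

    def test_dimension_mismatch_errors(self):
        snn = snn_from_dense([[1]])
        with pytest.raises(ValueError, match="dim|match"):
            attention_scores(np.ones((1, 3)), np.ones((2, 2)), np.ones(2), np.ones(2), snn)


class TestNormalizeAttention:
    def test_isolated_spot_gets_unit_self_attention(self):
        snn = snn_from_dense(np.eye(3))
        att = normalize_attention(np.array([0.2, 0.9, 0.1]), snn)
        np.testing.assert_allclose(att, 1.0)

    def test_uniform_scores_split_evenly(self):
        snn = snn_from_dense([[1, 1, 1], [1, 1, 0], [1, 0, 1]])
        att = normalize_attention(np.full(snn.n_edges, 0.7), snn)
        recv, _ = snn.edge_arrays()
        np.testing.assert_allclose(att[recv == 0], 1 / 3)
        np.testing.assert_allclose(att[recv == 1], 1 / 2)

    def test_closed_form_softmax(self):
        # scores [0, ln 2] -> weights [1/3, 2/3]
        snn = snn_from_dense([[1, 1], [1, 1]])
        recv, neigh = snn.edge_arrays()
        e = np.zeros(4)
        e[(recv == 0) & (neigh == 1)] = np.log(2.0)
        att = normalize_attention(e, snn)
        np.testing.assert_allclose(att[recv == 0], [1 / 3, 2 / 3])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        snn = random_snn(rng, 30)
        att = normalize_attention(rng.random(snn.n_edges), snn)
        recv, _ = snn.edge_arrays()
        sums = np.zeros(30)
        np.add.at(sums, recv, att)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestBlendAttention:
    def test_endpoints_and_default(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(10), rng.random(10)
        np.testing.assert_array_equal(blend_attention(a, b, 0.0), a)
        np.testing.assert_array_equal(blend_attention(a, b, 1.0), b)
        np.testing.assert_allclose(blend_attention(a, b, 0.5), (a + b) / 2)

    def test_alpha_out_of_range_errors(self):
        with pytest.raises(ValueError, match="alpha"):
            blend_attention(np.ones(2), np.ones(2), 1.5)

    def test_pruned_edges_keep_spatial_share_only(self):
        snn = snn_from_dense([[1, 1], [1, 1]])
        aware = snn_from_dense(np.eye(2))
        a_sp = np.array([0.5, 0.5, 0.5, 0.5])
        a_aw = np.array([1.0, 1.0])
        out = blend_attention(a_sp, a_aw, 0.5, snn=snn, aware_snn=aware)
        recv, neigh = snn.edge_arrays()
        np.testing.assert_allclose(out[recv == neigh], 0.75)
        np.testing.assert_allclose(out[recv != neigh], 0.25)


class TestEncodeDecode:
    def test_self_attention_identity_weights(self):
        # all mass on self-loops + identity weights + identity activation
        snn = snn_from_dense(np.eye(4))
        params = ModelParams([3, 3, 3], [np.eye(3), np.eye(3)], [np.zeros(3)], [np.zeros(3)])
        x = np.random.default_rng(6).normal(size=(4, 3))
        att = normalize_attention(np.zeros(4), snn)
        ident = lambda v: v
        emb = encode(x, params, [att], snn, activation=ident)
        np.testing.assert_allclose(emb, x)
        np.testing.assert_allclose(decode(emb, params, [att], snn, activation=ident), x)

    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(7)
        snn = random_snn(rng, 6)
        params = ModelParams.initialize([4, 5, 2], rng)
        x = np.zeros((6, 4))
        att = normalize_attention(
            attention_scores(x, params.weights[0], params.att_v_self[0],
                             params.att_v_neigh[0], snn),
            snn,
        )
        np.testing.assert_allclose(encode(x, params, [att], snn), 0.0, atol=1e-12)

    def test_tied_decoder_weights_are_transposes(self):
        params = ModelParams.initialize([4, 5, 2], np.random.default_rng(8))
        for enc, dec in zip(params.weights, params.decoder_weights()):
            assert dec.base is enc or np.shares_memory(dec, enc)
            np.testing.assert_array_equal(dec, enc.T)

    @pytest.mark.parametrize("seed", range(20))
    def test_dense_oracle_equivalence(self, seed):
        """Sparse edge-wise forward equals the dense attention-matrix oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        g = int(rng.integers(2, 9))
        snn = random_snn(rng, n)
        params = ModelParams.initialize([g, 5, 3], rng)
        x = rng.normal(size=(n, g))
        emb, recon, _ = forward(x, params, snn)
        emb_o, recon_o = dense_oracle(x, params, snn)
        np.testing.assert_allclose(emb, emb_o, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(recon, recon_o, rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_oracle_equivalence_aware(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 16))
        snn = random_snn(rng, n, p=0.5)
        labels = stgat.PreClusterLabels(rng.integers(0, 2, n), 0.2)
        aware = stgat.prune_to_aware_snn(snn, labels)
        params = ModelParams.initialize([4, 5, 3], rng)
        x = rng.normal(size=(n, 4))
        emb, recon, _ = forward(x, params, snn, aware, alpha=0.5)
        emb_o, recon_o = dense_oracle(x, params, snn, alpha=0.5, aware_snn=aware)
        np.testing.assert_allclose(emb, emb_o, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(recon, recon_o, rtol=1e-5, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        n = 12
        snn = random_snn(rng, n)
        params = ModelParams.initialize([5, 6, 3], rng)
        x = rng.normal(size=(n, 5))
        perm = rng.permutation(n)
        snn_p = snn_from_dense(snn.adjacency.toarray()[np.ix_(perm, perm)])
        emb, recon, _ = forward(x, params, snn)
        emb_p, recon_p, _ = forward(x[perm], params, snn_p)
        np.testing.assert_allclose(emb_p, emb[perm], rtol=1e-10)
        np.testing.assert_allclose(recon_p, recon[perm], rtol=1e-10)

    def test_locality_fuzz(self):
        """Perturbing a non-neighbor never changes a spot's layer-1 output."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            snn = random_snn(rng, n, p=0.25)
            params = ModelParams.initialize([3, 4, 2], rng)
            x = rng.normal(size=(n, 3))
            i = int(rng.integers(n))
            non_neighbors = np.setdiff1d(np.arange(n), snn.neighbor_set(i))
            if len(non_neighbors) == 0:
                continue
            j = int(rng.choice(non_neighbors))
            x2 = x.copy()
            x2[j] += rng.normal(size=3) * 10

            def layer1(inp):
                e = attention_scores(
                    inp, params.weights[0], params.att_v_self[0],
                    params.att_v_neigh[0], snn,
                )
                att = normalize_attention(e, snn)
                recv, neigh = snn.edge_arrays()
                z = inp @ params.weights[0]
                agg = np.zeros_like(z)
                np.add.at(agg, recv, z[neigh] * att[:, None])
                return agg

            np.testing.assert_array_equal(layer1(x)[i], layer1(x2)[i])


class TestReconstructionLoss:
    @pytest.mark.parametrize(
        "x,xh,sq,nrm",
        [
            ([[1.0, 0.0]], [[0.0, 0.0]], 1.0, 1.0),
            ([[3.0, 4.0]], [[0.0, 0.0]], 25.0, 5.0),
            ([[1.0, 2.0], [3.0, 4.0]], [[1.0, 2.0], [3.0, 4.0]], 0.0, 0.0),
        ],
    )
    def test_hand_values(self, x, xh, sq, nrm):
        assert reconstruction_loss(x, xh, "squared") == pytest.approx(sq)
        assert reconstruction_loss(x, xh, "norm") == pytest.approx(nrm)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruction_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestTraining:
    def test_loss_decreases(self, small_expr, small_snn):
        res = train(
            small_expr, small_snn,
            config=TrainingConfig(hidden_dims=(32, 8), n_iterations=60, seed=0),
        )
        assert res.loss_history[-1] < res.loss_history[0]
        assert res.embeddings.values.shape == (small_expr.n_spots, 8)
        assert res.reconstruction.values.shape == small_expr.values.shape

    def test_training_is_seed_reproducible(self, small_expr, small_snn):
        cfg = TrainingConfig(hidden_dims=(16, 4), n_iterations=10, seed=3)
        a = train(small_expr, small_snn, config=cfg)
        b = train(small_expr, small_snn, config=cfg)
        np.testing.assert_array_equal(a.embeddings.values, b.embeddings.values)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)

    def test_attention_rows_sum_to_one_every_iteration(self, small_expr, small_snn):
        recv, _ = small_snn.edge_arrays()
        deviations = []

        def cb(it, loss, attmap):
            sums = np.zeros(small_snn.n_spots)
            np.add.at(sums, recv, attmap.layers[0])
            deviations.append(np.abs(sums - 1).max())

        train(
            small_expr, small_snn,
            config=TrainingConfig(hidden_dims=(16, 4), n_iterations=25, seed=0),
            callback=cb,
        )
        assert len(deviations) == 25
        assert max(deviations) < 1e-6

    def test_rank1_signal_denoising(self):
        """Reconstruction tracks a shared program better than the noisy input."""
        rng = np.random.default_rng(12)
        n, g = 80, 20
        program = rng.uniform(0.5, 2.0, size=g)
        signal = np.outer(np.ones(n), program)
        noisy = signal + rng.normal(0, 0.3, size=(n, g))
        coords = rng.uniform(0, 9, size=(n, 2))
        snn = build_radius_snn(coords, 2.0)
        expr = ExpressionMatrix(
            noisy,
            np.array([f"g{i}" for i in range(g)], object),
            np.array([f"s{i}" for i in range(n)], object),
        )
        res = train(
            expr, snn, config=TrainingConfig(hidden_dims=(16, 4), n_iterations=400,
                                             seed=0, learning_rate=1e-3),
        )
        r_noisy = np.corrcoef(res.reconstruction.values.ravel(), noisy.ravel())[0, 1]
        r_signal = np.corrcoef(res.reconstruction.values.ravel(), signal.ravel())[0, 1]
        assert r_signal > r_noisy

    def test_nonfinite_input_aborts(self, small_snn):
        bad = ExpressionMatrix(
            np.full((small_snn.n_spots, 3), 1e300),
            np.array(["a", "b", "c"], object),
            np.array([f"s{i}" for i in range(small_snn.n_spots)], object),
        )
        with pytest.raises(FloatingPointError):
            train(bad, small_snn, config=TrainingConfig(hidden_dims=(4, 2), n_iterations=3))
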
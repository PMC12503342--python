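"""Network components and losses vs hand-computed oracles and closed forms."""

import numpy as np
import pytest
import scipy.sparse as sp

from spami import _tensor as T
from spami._tensor import Tensor
from spami.graph import build_knn_graph, normalize_adjacency
from spami.model import (
    AttentionFusion,
    BilinearDiscriminator,
    GCNDecoder,
    GCNEncoder,
    LossWeights,
    ModalityEmbedding,
    attention_fuse,
    contrastive_loss,
    correspondence_loss,
    discriminate,
    local_readout,
    reconstruction_loss,
)

RNG = np.random.default_rng(0)


def make_encoder(d_in, hidden, latent, seed=0, dropout=0.0):
    return GCNEncoder(d_in, hidden, latent, dropout, np.random.default_rng(seed))


class TestGcnEncode:
    def test_single_node_identity_weights_pass_through(self):
        enc = make_encoder(2, 2, 2)
        enc.W1.data = np.eye(2)
        enc.W2.data = np.eye(2)
        norm = sp.csr_matrix(np.array([[1.0]]))
        X = np.array([[0.3, 1.7]])
        out = enc.forward(X, norm).data
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_zero_input_zero_bias_gives_zero(self):
        enc = make_encoder(3, 4, 2)
        norm = normalize_adjacency(sp.csr_matrix((5, 5)))
        out = enc.forward(np.zeros((5, 3)), norm).data
        np.testing.assert_allclose(out, 0.0)

    def test_path_graph_matches_dense_oracle(self):
        # 3-node path, hand-set 2x2 weights, oracle = explicit matrix algebra
        A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
        M = normalize_adjacency(A).toarray()
        enc = make_encoder(2, 2, 2)
        W1 = np.array([[0.5, -1.0], [2.0, 0.3]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.5, 0.0], [-0.7, 1.0]])
        b2 = np.array([0.0, 0.05])
        enc.W1.data, enc.b1.data = W1, b1
        enc.W2.data, enc.b2.data = W2, b2
        X = np.array([[1.0, 0.0], [0.5, -0.5], [0.0, 2.0]])
        h1 = np.maximum(M @ X @ W1 + b1, 0)
        expected = np.maximum(M @ h1 @ W2 + b2, 0)
        out = enc.forward(X, sp.csr_matrix(M)).data
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_dropout_only_in_training_mode(self):
        enc = make_encoder(4, 4, 3, dropout=0.5)
        norm = normalize_adjacency(sp.csr_matrix((6, 6)))
        X = RNG.normal(size=(6, 4))
        a = enc.forward(X, norm).data
        b = enc.forward(X, norm).data
        np.testing.assert_array_equal(a, b)  # eval mode is deterministic
        t = enc.forward(X, norm, training=True, rng=np.random.default_rng(1)).data
        assert not np.allclose(a, t)


class TestLocalReadout:
    def test_zero_neighbor_embedding_gives_half(self):
        coords = np.array([[0.0, 0], [1, 0]])
        g = build_knn_graph(coords, r=1)
        Z = np.array([[3.0, -2.0], [0.0, 0.0]])
        out = local_readout(Z, g).data
        np.testing.assert_allclose(out[0], 0.5)  # only neighbor is the zero row

    def test_identical_neighbors_give_sigmoid_of_v(self, rng):
        coords = rng.uniform(size=(6, 2))
        g = build_knn_graph(coords, r=5)  # complete graph
        v = np.array([0.7, -1.2, 0.1])
        Z = np.tile(v, (6, 1))
        out = local_readout(Z, g).data
        np.testing.assert_allclose(out, 1 / (1 + np.exp(-Z)), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        coords = rng.uniform(size=(10, 2))
        g = build_knn_graph(coords, r=3)
        Z = rng.normal(size=(10, 4))
        out = local_readout(Z, g).data
        A = g.adjacency.toarray()
        for i in range(10):
            nbrs = np.flatnonzero(A[i])
            expected = 1 / (1 + np.exp(-Z[nbrs].mean(axis=0)))
            np.testing.assert_allclose(out[i], expected, atol=1e-10)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        coords = rng.uniform(size=(20, 2))
        g = build_knn_graph(coords, r=3)
        out = local_readout(rng.normal(size=(20, 6)), g).data
        assert np.all(out > 0) and np.all(out < 1)


class TestDiscriminator:
    def test_zero_embedding_gives_half(self, rng):
        disc = BilinearDiscriminator(4, rng)
        p = discriminate(np.zeros(4), rng.normal(size=4), disc)
        assert p[0] == pytest.approx(0.5)

    def test_orthogonal_pair_with_identity_gives_half(self):
        disc = BilinearDiscriminator(2, np.random.default_rng(0))
        disc.W.data = np.eye(2)
        p = discriminate(np.array([1.0, 0.0]), np.array([0.0, 1.0]), disc)
        assert p[0] == pytest.approx(0.5)

    def test_aligned_pair_monotone_to_one(self):
        disc = BilinearDiscriminator(3, np.random.default_rng(0))
        disc.W.data = np.eye(3)
        probs = [discriminate(c * np.ones(3), c * np.ones(3), disc)[0]
                 for c in (0.5, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(probs) > 0)
        assert probs[-1] > 0.999999


class TestContrastiveLoss:
    def test_uninformative_discriminator_gives_two_ln_two(self, rng):
        n, d = 8, 4
        disc = BilinearDiscriminator(d, rng)
        disc.W.data = np.zeros((d, d))  # every score 0.5
        emb = ModalityEmbedding(
            Z=Tensor(rng.normal(size=(n, d))),
            Z_shuffle=Tensor(rng.normal(size=(n, d))),
            local=Tensor(rng.uniform(0.1, 0.9, size=(n, d))),
            local_shuffle=Tensor(rng.uniform(0.1, 0.9, size=(n, d))),
        )
        loss = contrastive_loss(emb, disc)
        assert loss.item() == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_confident_discriminator_drives_loss_to_zero(self):
        d = 2
        disc = BilinearDiscriminator(d, np.random.default_rng(0))
        disc.W.data = np.eye(d) * 50.0
        z = np.ones((4, d))
        emb = ModalityEmbedding(Z=Tensor(z), Z_shuffle=Tensor(-z),
                                local=Tensor(z), local_shuffle=Tensor(-z))
        # positives strongly aligned, negatives strongly anti-aligned
        assert contrastive_loss(emb, disc).item() < 1e-10

    def test_matches_manual_bce_oracle(self, rng):
        n, d = 2, 3
        disc = BilinearDiscriminator(d, rng)
        Z = rng.normal(size=(n, d))
        Zs = rng.normal(size=(n, d))
        L = rng.uniform(0.2, 0.8, size=(n, d))
        Ls = rng.uniform(0.2, 0.8, size=(n, d))
        emb = ModalityEmbedding(Z=Tensor(Z), Z_shuffle=Tensor(Zs),
                                local=Tensor(L), local_shuffle=Tensor(Ls))
        got = contrastive_loss(emb, disc).item()

        def sig(x):
            return 1 / (1 + np.exp(-x))

        W = disc.W.data
        acc = 0.0
        for i in range(n):
            acc += np.log(sig(Z[i] @ W @ L[i])) + np.log(1 - sig(Z[i] @ W @ Ls[i]))
        clean = -acc / (2 * n)
        acc = 0.0
        for i in range(n):
            acc += np.log(sig(Zs[i] @ W @ Ls[i])) + np.log(1 - sig(Zs[i] @ W @ L[i]))
        shuffled = -acc / (2 * n)
        assert got == pytest.approx(clean + shuffled, abs=1e-6)


class TestAttention:
    def test_identical_inputs_share_weight_equally(self, rng):
        att = AttentionFusion(4, 3, rng)
        Z = rng.normal(size=(10, 4))
        res = attention_fuse(Z, Z, att)
        np.testing.assert_allclose(res.alpha, 0.5, atol=1e-12)
        np.testing.assert_allclose(res.Z, Z, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        att = AttentionFusion(6, 5, rng)
        res = attention_fuse(rng.normal(size=(100, 6)), rng.normal(size=(100, 6)), att)
        np.testing.assert_allclose(res.alpha.sum(axis=1), 1.0, atol=1e-7)
        assert np.all(res.alpha > 0) and np.all(res.alpha < 1)

    def test_fused_matches_per_spot_weighted_sum(self, rng):
        att = AttentionFusion(5, 4, rng)
        Z1 = rng.normal(size=(12, 5))
        Z2 = rng.normal(size=(12, 5))
        res = attention_fuse(Z1, Z2, att)
        for i in range(12):
            expected = res.alpha[i, 0] * Z1[i] + res.alpha[i, 1] * Z2[i]
            np.testing.assert_allclose(res.Z[i], expected, atol=1e-10)


class TestDecoderAndLosses:
    def test_zero_latent_zero_bias_decodes_to_zero(self, rng):
        dec = GCNDecoder(3, 4, 6, rng)
        norm = normalize_adjacency(sp.csr_matrix((5, 5)))
        out = dec.forward(np.zeros((5, 3)), norm).data
        np.testing.assert_allclose(out, 0.0)

    def test_decoder_matches_dense_oracle(self, rng):
        A = sp.csr_matrix(np.array([[0, 1], [1, 0]], float))
        M = normalize_adjacency(A).toarray()
        dec = GCNDecoder(2, 2, 3, rng)
        Z = rng.normal(size=(2, 2))
        h1 = np.maximum(M @ Z @ dec.W1.data + dec.b1.data, 0)
        expected = M @ h1 @ dec.W2.data + dec.b2.data
        np.testing.assert_allclose(dec.forward(Z, sp.csr_matrix(M)).data,
                                   expected, atol=1e-8)

    def test_reconstruction_perfect_is_zero(self, rng):
        X1 = rng.normal(size=(4, 3))
        X2 = rng.normal(size=(4, 2))
        w = LossWeights()
        loss = reconstruction_loss(X1, X2, Tensor(X1), Tensor(X2), w)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_single_entry_arithmetic(self):
        X1 = np.zeros((2, 3))
        Y1 = np.zeros((2, 3))
        Y1[0, 0] = 2.0
        w = LossWeights(lambda1=1.0, lambda2=1.0)
        loss = reconstruction_loss(X1, np.zeros((2, 2)), Tensor(Y1),
                                   Tensor(np.zeros((2, 2))), w)
        assert loss.item() == pytest.approx(2.0)

    def test_reconstruction_matches_loop_oracle(self, rng):
        X1, Y1 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        X2, Y2 = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        w = LossWeights(lambda1=2.0, lambda2=3.0)
        got = reconstruction_loss(X1, X2, Tensor(Y1), Tensor(Y2), w).item()
        expected = (2.0 * np.mean([(X1[i] - Y1[i]) @ (X1[i] - Y1[i]) for i in range(5)])
                    + 3.0 * np.mean([(X2[i] - Y2[i]) @ (X2[i] - Y2[i]) for i in range(5)]))
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("relation,expected_factor", [
        ("equal", 0.0), ("negated", 2.0), ("orthogonal", 1.0)])
    def test_correspondence_canonical_relations(self, relation, expected_factor, rng):
        mu = 5.0
        Z1 = rng.normal(size=(6, 4))
        if relation == "equal":
            Z2 = Z1.copy()
        elif relation == "negated":
            Z2 = -Z1
        else:
            Z2 = np.zeros_like(Z1)
            Z2[:, 2:] = rng.normal(size=(6, 2))
            Z1[:, 2:] = 0.0
        loss = correspondence_loss(Z1, Z2, mu).item()
        assert loss == pytest.approx(expected_factor * mu, abs=1e-5)


class TestFullLossGradient:
    def test_autodiff_matches_finite_differences_end_to_end(self, rng):
        """Finite-difference check of the total loss on a tiny network."""
        from tests.test_tensor import finite_diff_grad

        n, d, hid, lat = 6, 3, 4, 2
        coords = rng.uniform(size=(n, 2))
        g = build_knn_graph(coords, r=2)
        X1 = rng.normal(size=(n, d))
        X2 = rng.normal(size=(n, d))
        enc1 = make_encoder(d, hid, lat, seed=1)
        enc2 = make_encoder(d, hid, lat, seed=2)
        disc1 = BilinearDiscriminator(lat, np.random.default_rng(3))
        att = AttentionFusion(lat, 3, np.random.default_rng(4))
        dec1 = GCNDecoder(lat, hid, d, np.random.default_rng(5))
        w = LossWeights()
        perm = np.random.default_rng(6).permutation(n)

        def build():
            Z1 = enc1.forward(X1, g.normalized)
            Z2 = enc2.forward(X2, g.normalized)
            Z1s = enc1.forward(X1[perm], g.normalized)
            emb = ModalityEmbedding(Z=Z1, Z_shuffle=Z1s,
                                    local=local_readout(Z1, g),
                                    local_shuffle=local_readout(Z1s, g))
            fused, _ = att.forward(Z1, Z2)
            Y1 = dec1.forward(fused, g.normalized)
            d1 = Tensor(X1) - Y1
            rec = T.mul(T.tsum(T.mul(d1, d1)), w.lambda1 / n)
            return (T.mul(contrastive_loss(emb, disc1), w.gamma1) + rec
                    + correspondence_loss(Z1, Z2, w.mu))

        params = (enc1.parameters() + enc2.parameters() + disc1.parameters()
                  + att.parameters() + dec1.parameters())
        # move biases off zero so no ReLU preactivation sits exactly on the
        # kink, where the finite-difference oracle is undefined
        jitter = np.random.default_rng(8)
        for p in params:
            if p.data.ndim == 1:
                p.data = p.data + jitter.uniform(0.05, 0.2, size=p.data.shape)
        loss = build()
        loss.backward()
        check = np.random.default_rng(7)
        for p in params:
            if p.grad is None:
                continue
            fd = finite_diff_grad(lambda: build().item(), p.data, eps=1e-6)
            # compare on up to 10 random entries per parameter
            flat_g, flat_fd = p.grad.ravel(), fd.ravel()
            idx = check.choice(flat_g.size, size=min(10, flat_g.size), replace=False)
            scale = max(np.abs(flat_fd[idx]).max(), 1e-3)
            np.testing.assert_allclose(flat_g[idx], flat_fd[idx],
                                       rtol=1e-4, atol=1e-4 * scale)


class TestStructuralInvariants:
    def test_permutation_equivariance_eval_mode(self, rng):
        n, d = 20, 5
        coords = rng.uniform(size=(n, 2))
        X = rng.normal(size=(n, d))
        enc = make_encoder(d, 6, 3, seed=3)
        g = build_knn_graph(coords, r=3)
        Z = enc.forward(X, g.normalized).data
        perm = rng.permutation(n)
        g2 = build_knn_graph(coords[perm], r=3)
        Z2 = enc.forward(X[perm], g2.normalized).data
        np.testing.assert_allclose(Z2, Z[perm], atol=1e-10)

    def test_eval_forward_is_bitwise_stable(self, rng):
        coords = rng.uniform(size=(15, 2))
        g = build_knn_graph(coords, r=3)
        X = rng.normal(size=(15, 4))
        enc = make_encoder(4, 5, 3, seed=0)
        a = enc.forward(X, g.normalized).data
        b = enc.forward(X, g.normalized).data
        assert np.array_equal(a, b)
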
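"""Network components and losses of the integration model.

Per modality: a two-layer graph-convolutional encoder (ReLU after each
layer, input dropout while training) maps the reduced features into a
shared latent dimension; a local-context readout (sigmoid of the neighbor
mean) and a bilinear discriminator supply a deep-graph-infomax style
contrastive objective against a feature-shuffled corrupted view.  A shared
attention scorer fuses the two modality embeddings into one per-spot convex
combination, which symmetric two-layer GCN decoders project back to each
modality's feature space.  The three loss terms — contrastive, squared-error
reconstruction, and cosine correspondence — are weighted by
(gamma1, gamma2, lambda1, lambda2, mu).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import _tensor as T
from ._tensor import Tensor
from .graph import SpatialGraph

__all__ = [
    "LossWeights",
    "GCNEncoder",
    "GCNDecoder",
    "AttentionFusion",
    "BilinearDiscriminator",
    "ModalityEmbedding",
    "FusionResult",
    "gcn_encode",
    "local_readout",
    "discriminate",
    "contrastive_loss",
    "attention_fuse",
    "gcn_decode",
    "reconstruction_loss",
    "correspondence_loss",
    "total_loss",
    "glorot",
]


@dataclass
class LossWeights:
    """Weights (gamma1, gamma2, lambda1, lambda2, mu) of the loss terms.

    Defaults are the simulated-data setting [1, 1, 10, 10, 5], which is
    also the model's global default.
    """

    gamma1: float = 1.0
    gamma2: float = 1.0
    lambda1: float = 10.0
    lambda2: float = 10.0
    mu: float = 5.0

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "lambda1", "lambda2", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be nonnegative")

    def as_list(self) -> list[float]:
        return [self.gamma1, self.gamma2, self.lambda1, self.lambda2, self.mu]

    @classmethod
    def from_list(cls, w) -> "LossWeights":
        return cls(*map(float, w))


@dataclass
class ModalityEmbedding:
    """Clean/corrupted embeddings and their local-context readouts."""

    Z: Tensor
    Z_shuffle: Tensor
    local: Tensor
    local_shuffle: Tensor


@dataclass
class FusionResult:
    """Fused embedding and per-spot modality attention weights."""

    Z: np.ndarray
    alpha: np.ndarray | None


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier-uniform weight initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class GCNEncoder:
    """Two-layer GCN d_in -> hidden -> latent with ReLU and input dropout."""

    def __init__(self, d_in: int, hidden_dim: int, latent_dim: int,
                 dropout: float, rng: np.random.Generator):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.dropout = dropout
        self.W1 = glorot(rng, d_in, hidden_dim)
        self.b1 = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.W2 = glorot(rng, hidden_dim, latent_dim)
        self.b2 = Tensor(np.zeros(latent_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X, normalized: sp.spmatrix, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = X if isinstance(X, Tensor) else Tensor(X)
        if training and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            h = T.dropout(h, self.dropout, rng)
        h = T.relu(T.spmm(normalized, h) @ self.W1 + self.b1)
        h = T.relu(T.spmm(normalized, h) @ self.W2 + self.b2)
        return h


class GCNDecoder:
    """Symmetric two-layer GCN latent -> hidden -> d_out (no dropout)."""

    def __init__(self, latent_dim: int, hidden_dim: int, d_out: int,
                 rng: np.random.Generator):
        self.W1 = glorot(rng, latent_dim, hidden_dim)
        self.b1 = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.W2 = glorot(rng, hidden_dim, d_out)
        self.b2 = Tensor(np.zeros(d_out), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, Z, normalized: sp.spmatrix) -> Tensor:
        h = Z if isinstance(Z, Tensor) else Tensor(Z)
        h = T.relu(T.spmm(normalized, h) @ self.W1 + self.b1)
        h = T.spmm(normalized, h) @ self.W2 + self.b2
        return h


class BilinearDiscriminator:
    """sigmoid(z^T W l): probability that (z, l) is a true spot/context pair."""

    def __init__(self, latent_dim: int, rng: np.random.Generator):
        self.W = glorot(rng, latent_dim, latent_dim)

    def parameters(self) -> list[Tensor]:
        return [self.W]

    def logits(self, Z, L) -> Tensor:
        """Row-wise bilinear scores z_i^T W l_i (pre-sigmoid)."""
        Z = Z if isinstance(Z, Tensor) else Tensor(Z)
        L = L if isinstance(L, Tensor) else Tensor(L)
        return T.tsum(T.mul(Z @ self.W, L), axis=1)


class AttentionFusion:
    """Shared per-spot scorer over modality embeddings, softmax-normalized.

    v_im = tanh(z_im W_v + b_v); u_im = v_im w_u + b_u; alpha_i = softmax_m(u_i);
    fused z_i = alpha_i1 z_i1 + alpha_i2 z_i2.
    """

    def __init__(self, latent_dim: int, attention_hidden_dim: int,
                 rng: np.random.Generator):
        self.Wv = glorot(rng, latent_dim, attention_hidden_dim)
        self.bv = Tensor(np.zeros(attention_hidden_dim), requires_grad=True)
        self.wu = glorot(rng, attention_hidden_dim, 1)
        self.bu = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.Wv, self.bv, self.wu, self.bu]

    def forward(self, Z1, Z2) -> tuple[Tensor, Tensor]:
        Z1 = Z1 if isinstance(Z1, Tensor) else Tensor(Z1)
        Z2 = Z2 if isinstance(Z2, Tensor) else Tensor(Z2)
        scores = []
        for Zm in (Z1, Z2):
            v = T.tanh(Zm @ self.Wv + self.bv)
            scores.append(v @ self.wu + self.bu)  # (N, 1)
        U = T.concat(scores, axis=1)              # (N, 2)
        alpha = T.softmax(U, axis=1)
        a1 = alpha[:, 0:1]
        a2 = alpha[:, 1:2]
        fused = T.mul(Z1, a1) + T.mul(Z2, a2)
        return fused, alpha


# -- functional surface -------------------------------------------------------


def gcn_encode(X: np.ndarray, normalized: sp.spmatrix, encoder: GCNEncoder,
               training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
    """Encode a feature matrix through a two-layer GCN."""
    return encoder.forward(X, normalized, training=training, rng=rng)


def _readout_matrix(graph: SpatialGraph, dtype) -> sp.csr_matrix:
    """Neighbor-averaging operator, cached on the graph per dtype."""
    cache = getattr(graph, "_readout_cache", None)
    if cache is None:
        cache = {}
        graph._readout_cache = cache
    key = np.dtype(dtype).str
    if key not in cache:
        A = graph.adjacency.tolil(copy=True)
        deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
        isolated = np.flatnonzero(deg == 0)
        for i in isolated:
            A[i, i] = 1.0
        deg[isolated] = 1.0
        M = sp.diags(1.0 / deg) @ A.tocsr()
        cache[key] = M.astype(dtype).tocsr()
    return cache[key]


def local_readout(Z, graph: SpatialGraph) -> Tensor:
    """Local context l_i = sigmoid(mean of the neighbors' embeddings).

    Isolated spots (none exist after symmetrized kNN construction, but the
    operation is defined defensively) fall back to sigmoid(z_i).
    """
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    M = _readout_matrix(graph, Z.data.dtype)
    return T.sigmoid(T.spmm(M, Z))


def discriminate(z: np.ndarray, l: np.ndarray, disc: BilinearDiscriminator) -> np.ndarray:
    """Probability score sigmoid(z^T W l) for one or more (z, l) pairs."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    l = np.atleast_2d(np.asarray(l, dtype=float))
    return T.sigmoid(disc.logits(Tensor(z), Tensor(l))).data


def contrastive_loss(emb: ModalityEmbedding, disc: BilinearDiscriminator) -> Tensor:
    """Binary cross-entropy mutual-information loss for one modality.

    L = −(1/2N) Σ_i [log Φ(z_i, l_i) + log(1 − Φ(z_i, l'_i))] plus the
    mirrored term for the shuffled view, computed with log-sigmoid forms so
    probabilities saturating at 0/1 cannot produce non-finite values.
    """
    n = emb.Z.shape[0]

    def half(Z, local, local_other) -> Tensor:
        pos = disc.logits(Z, local)          # positive pairs
        neg = disc.logits(Z, local_other)    # negative pairs
        s = T.tsum(T.log_sigmoid(pos)) + T.tsum(T.log_sigmoid(T.mul(neg, -1.0)))
        return T.mul(s, -1.0 / (2.0 * n))

    l_clean = half(emb.Z, emb.local, emb.local_shuffle)
    l_shuffle = half(emb.Z_shuffle, emb.local_shuffle, emb.local)
    return l_clean + l_shuffle


def attention_fuse(Z1, Z2, attention: AttentionFusion) -> FusionResult:
    """Fuse two modality embeddings; returns fused Z and alpha as arrays."""
    fused, alpha = attention.forward(Z1, Z2)
    return FusionResult(Z=fused.data.copy(), alpha=alpha.data.copy())


def gcn_decode(Z, normalized: sp.spmatrix, decoder1: GCNDecoder,
               decoder2: GCNDecoder) -> tuple[Tensor, Tensor]:
    """Decode the fused embedding back to both modality feature spaces."""
    return decoder1.forward(Z, normalized), decoder2.forward(Z, normalized)


def reconstruction_loss(X1, X2, Y1, Y2, weights: LossWeights) -> Tensor:
    """λ1 mean_i ||x_1i − y_1i||² + λ2 mean_i ||x_2i − y_2i||²."""
    X1 = X1 if isinstance(X1, Tensor) else Tensor(X1)
    X2 = X2 if isinstance(X2, Tensor) else Tensor(X2)
    n = X1.shape[0]
    if Y1.shape != X1.shape or Y2.shape != X2.shape:
        raise ValueError("reconstruction shapes do not match inputs")
    d1 = X1 - Y1
    d2 = X2 - Y2
    l1 = T.mul(T.tsum(T.mul(d1, d1)), weights.lambda1 / n)
    l2 = T.mul(T.tsum(T.mul(d2, d2)), weights.lambda2 / n)
    return l1 + l2


def correspondence_loss(Z1, Z2, mu: float, eps: float = 1e-12) -> Tensor:
    """μ (1 − mean_i cos(z_1i, z_2i)); zero-norm rows contribute cosine 0."""
    Z1 = Z1 if isinstance(Z1, Tensor) else Tensor(Z1)
    Z2 = Z2 if isinstance(Z2, Tensor) else Tensor(Z2)
    dots = T.tsum(T.mul(Z1, Z2), axis=1)
    n1 = T.sqrt(T.tsum(T.mul(Z1, Z1), axis=1) + eps)
    n2 = T.sqrt(T.tsum(T.mul(Z2, Z2), axis=1) + eps)
    cos = T.div(dots, T.mul(n1, n2))
    return T.mul(1.0 - T.tmean(cos), float(mu))


def total_loss(parts: dict[str, Tensor]) -> Tensor:
    """Sum of the weighted loss components (each already carries its weight)."""
    vals = list(parts.values())
    out = vals[0]
    for v in vals[1:]:
        out = out + v
    return out
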
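"""The integration estimator: joint training of encoders, attention,
discriminators and decoders under the combined loss.

`SpaMI` follows the scikit-learn estimator protocol: hyperparameters in
``__init__``, :meth:`fit` on a preprocessed modality pair, fitted arrays in
trailing-underscore attributes, :meth:`transform` returning the fused
embedding.  Training is full batch (real slices hold at most ~10k spots);
the corrupted feature permutations are redrawn every epoch from the seeded
stream, and the optimizer is Adam with default moments.
"""

from __future__ import annotations

import json
import hashlib

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import model as M
from ._tensor import Adam, Tensor
from . import _tensor as T
from .containers import SpatialOmicsPair
from .graph import SpatialGraph, build_knn_graph
from .model import LossWeights

__all__ = ["SpaMI"]


def _as_pair(X) -> SpatialOmicsPair:
    if isinstance(X, SpatialOmicsPair):
        return X
    if isinstance(X, (tuple, list)) and len(X) == 3:
        X1, X2, coords = X
        return SpatialOmicsPair(X1=np.asarray(X1, float), X2=np.asarray(X2, float),
                                coords=np.asarray(coords, float))
    raise TypeError(
        "X must be a SpatialOmicsPair or an (X1, X2, coords) tuple of arrays"
    )


class SpaMI(TransformerMixin, BaseEstimator):
    """Graph-contrastive spatial multi-omics integration.

    Parameters
    ----------
    hidden_dim, latent_dim : int
        Widths of the two GCN layers (shared by both modality encoders and
        the symmetric decoders).
    attention_hidden_dim : int
        Width of the attention scorer's hidden projection.
    dropout : float
        Input dropout probability during training (default 0.15).
    learning_rate, epochs : optimizer settings; defaults are the simulated-
        data preset (0.001, 1000).
    neighbor_r : int
        Spatial k-nearest-neighbor count (default 3).
    loss_weights : sequence or LossWeights
        (gamma1, gamma2, lambda1, lambda2, mu); default [1, 1, 10, 10, 5].
    single_modality_mode : {"off", "modality1", "modality2"}
        Restrict the model to one modality: attention fusion and the
        correspondence term are dropped.
    ablation : {"none", "no_cosine", "no_contrastive", "concat_fusion"}
        Remove one component for contribution studies; ``concat_fusion``
        replaces attention with plain concatenation (embedding has
        2 x latent_dim columns).
    random_state : int
        Seed for initialization, dropout and the corruption stream.

    Attributes
    ----------
    embedding_ : ndarray (n_spots, latent_dim or 2*latent_dim)
        Fused embedding in evaluation mode after training.
    attention_weights_ : ndarray (n_spots, 2) or None
        Per-spot modality attention weights (rows sum to 1).
    modality_embeddings_ : tuple of ndarray
        Per-modality latent matrices Z1, Z2 (eval mode).
    loss_history_ : dict[str, list[float]]
        Per-epoch values of each loss component and the total.
    graph_ : SpatialGraph
        The spatial neighbor graph used for training.
    """

    def __init__(self, *, hidden_dim: int = 256, latent_dim: int = 64,
                 attention_hidden_dim: int = 32, dropout: float = 0.15,
                 learning_rate: float = 0.001, epochs: int = 1000,
                 neighbor_r: int = 3, loss_weights=(1.0, 1.0, 10.0, 10.0, 5.0),
                 single_modality_mode: str = "off", ablation: str = "none",
                 random_state: int = 0, dtype: str = "float32"):
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.attention_hidden_dim = attention_hidden_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.neighbor_r = neighbor_r
        self.loss_weights = loss_weights
        self.single_modality_mode = single_modality_mode
        self.ablation = ablation
        self.random_state = random_state
        self.dtype = dtype

    # -- internals ------------------------------------------------------------

    def _weights(self) -> LossWeights:
        w = self.loss_weights
        if isinstance(w, LossWeights):
            return w
        return LossWeights.from_list(list(w))

    def _build_components(self, d1: int, d2: int, rng: np.random.Generator) -> dict:
        mode = self.single_modality_mode
        if mode not in ("off", "modality1", "modality2"):
            raise ValueError(f"invalid single_modality_mode {mode!r}")
        if self.ablation not in ("none", "no_cosine", "no_contrastive", "concat_fusion"):
            raise ValueError(f"invalid ablation {self.ablation!r}")
        if mode != "off" and self.ablation != "none":
            raise ValueError("single_modality_mode and ablation are mutually exclusive")
        comp: dict = {}
        fused_dim = self.latent_dim
        if mode == "off" and self.ablation == "concat_fusion":
            fused_dim = 2 * self.latent_dim
        use1 = mode in ("off", "modality1")
        use2 = mode in ("off", "modality2")
        if use1:
            comp["enc1"] = M.GCNEncoder(d1, self.hidden_dim, self.latent_dim,
                                        self.dropout, rng)
            comp["disc1"] = M.BilinearDiscriminator(self.latent_dim, rng)
            comp["dec1"] = M.GCNDecoder(fused_dim, self.hidden_dim, d1, rng)
        if use2:
            comp["enc2"] = M.GCNEncoder(d2, self.hidden_dim, self.latent_dim,
                                        self.dropout, rng)
            comp["disc2"] = M.BilinearDiscriminator(self.latent_dim, rng)
            comp["dec2"] = M.GCNDecoder(fused_dim, self.hidden_dim, d2, rng)
        if mode == "off" and self.ablation != "concat_fusion":
            comp["attention"] = M.AttentionFusion(self.latent_dim,
                                                  self.attention_hidden_dim, rng)
        return comp

    def _parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for c in self._components_.values():
            params.extend(c.parameters())
        return params

    def _fuse(self, Z1, Z2):
        """Fused embedding per mode/ablation; returns (Tensor, alpha or None)."""
        mode = self.single_modality_mode
        if mode == "modality1":
            return Z1, None
        if mode == "modality2":
            return Z2, None
        if self.ablation == "concat_fusion":
            return T.concat([Z1, Z2], axis=1), None
        fused, alpha = self._components_["attention"].forward(Z1, Z2)
        return fused, alpha

    def _forward_losses(self, X1, X2, graph: SpatialGraph, norm, weights: LossWeights,
                        training: bool, rng: np.random.Generator | None):
        comp = self._components_
        mode = self.single_modality_mode
        use_contrastive = self.ablation != "no_contrastive"
        use_cosine = mode == "off" and self.ablation not in ("no_cosine",)
        parts: dict[str, Tensor] = {}

        def encode_modality(Xj, enc, disc, gamma):
            Z = enc.forward(Xj, norm, training=training, rng=rng)
            if not use_contrastive:
                return Z, None
            perm = (rng.permutation(Xj.shape[0]) if training and rng is not None
                    else np.arange(Xj.shape[0]))
            Zs = enc.forward(Xj[perm], norm, training=training, rng=rng)
            emb = M.ModalityEmbedding(
                Z=Z, Z_shuffle=Zs,
                local=M.local_readout(Z, graph),
                local_shuffle=M.local_readout(Zs, graph),
            )
            return Z, T.mul(M.contrastive_loss(emb, disc), gamma)

        Z1 = Z2 = None
        contrast_terms = []
        if "enc1" in comp:
            Z1, c1 = encode_modality(X1, comp["enc1"], comp["disc1"], weights.gamma1)
            if c1 is not None:
                contrast_terms.append(c1)
        if "enc2" in comp:
            Z2, c2 = encode_modality(X2, comp["enc2"], comp["disc2"], weights.gamma2)
            if c2 is not None:
                contrast_terms.append(c2)
        if contrast_terms:
            total_c = contrast_terms[0]
            for t in contrast_terms[1:]:
                total_c = total_c + t
            parts["contrastive"] = total_c

        fused, alpha = self._fuse(Z1 if Z1 is not None else Z2,
                                  Z2 if Z2 is not None else Z1)

        if mode == "off":
            Y1 = comp["dec1"].forward(fused, norm)
            Y2 = comp["dec2"].forward(fused, norm)
            parts["reconstruction"] = M.reconstruction_loss(X1, X2, Y1, Y2, weights)
        elif mode == "modality1":
            Y1 = comp["dec1"].forward(fused, norm)
            d = Tensor(X1) - Y1
            parts["reconstruction"] = T.mul(T.tsum(T.mul(d, d)),
                                            weights.lambda1 / X1.shape[0])
        else:
            Y2 = comp["dec2"].forward(fused, norm)
            d = Tensor(X2) - Y2
            parts["reconstruction"] = T.mul(T.tsum(T.mul(d, d)),
                                            weights.lambda2 / X2.shape[0])

        if use_cosine:
            parts["correspondence"] = M.correspondence_loss(Z1, Z2, weights.mu)

        return parts, fused, alpha, (Z1, Z2)

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y=None, graph: SpatialGraph | None = None):
        """Train on a preprocessed modality pair.

        Parameters
        ----------
        X : SpatialOmicsPair or (X1, X2, coords) tuple
            Reduced per-modality feature matrices and shared coordinates.
        y : ignored
            Present for scikit-learn API compatibility.
        graph : SpatialGraph, optional
            Precomputed spatial graph; built from ``X.coords`` with
            ``neighbor_r`` neighbors when omitted.
        """
        pair = _as_pair(X)
        X1 = np.asarray(pair.X1, dtype=float)
        X2 = np.asarray(pair.X2, dtype=float)
        if not (np.all(np.isfinite(X1)) and np.all(np.isfinite(X2))):
            raise ValueError("input feature matrices must be finite")
        weights = self._weights()
        if graph is None:
            graph = build_knn_graph(pair.coords, self.neighbor_r)

        # optimization runs in the configured dtype (float32 default, ~2x
        # faster dense algebra); the final eval pass is in float64
        work_dtype = np.dtype(self.dtype)
        norm = graph.normalized.astype(work_dtype)
        X1w = X1.astype(work_dtype)
        X2w = X2.astype(work_dtype)

        rng = np.random.default_rng(self.random_state)
        self._components_ = self._build_components(X1.shape[1], X2.shape[1], rng)
        params = self._parameters()
        for p in params:
            p.data = p.data.astype(work_dtype)
        opt = Adam(params, lr=self.learning_rate)

        history: dict[str, list[float]] = {}
        for epoch in range(self.epochs):
            parts, _, _, _ = self._forward_losses(
                X1w, X2w, graph, norm, weights, training=True, rng=rng)
            loss = M.total_loss(parts)
            if not np.isfinite(loss.data):
                comps = {k: float(v.data) for k, v in parts.items()}
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: components {comps}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in parts.items():
                history.setdefault(k, []).append(float(v.data))
            history.setdefault("total", []).append(float(loss.data))

        # final evaluation-mode pass at full precision
        for p in params:
            p.data = p.data.astype(np.float64)
        parts, fused, alpha, (Z1, Z2) = self._forward_losses(
            X1, X2, graph, graph.normalized, weights, training=False, rng=None)
        self.embedding_ = fused.data.copy()
        self.attention_weights_ = None if alpha is None else alpha.data.copy()
        self.modality_embeddings_ = (
            None if Z1 is None else Z1.data.copy(),
            None if Z2 is None else Z2.data.copy(),
        )
        self.loss_history_ = history
        self.graph_ = graph
        self.n_features_in_ = X1.shape[1] + X2.shape[1]
        self._input_dims_ = (X1.shape[1], X2.shape[1])
        return self

    def transform(self, X=None, graph: SpatialGraph | None = None) -> np.ndarray:
        """Fused embedding; for new data, an eval-mode forward pass."""
        check_is_fitted(self, "embedding_")
        if X is None:
            return self.embedding_
        pair = _as_pair(X)
        if graph is None:
            graph = build_knn_graph(pair.coords, self.neighbor_r)
        parts, fused, _, _ = self._forward_losses(
            np.asarray(pair.X1, float), np.asarray(pair.X2, float),
            graph, graph.normalized, self._weights(), training=False, rng=None)
        return fused.data.copy()

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).embedding_

    def decode(self) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Eval-mode decoder outputs in each modality's reduced feature space."""
        check_is_fitted(self, "embedding_")
        comp = self._components_
        fused = Tensor(self.embedding_)
        norm = self.graph_.normalized
        Y1 = comp["dec1"].forward(fused, norm).data if "dec1" in comp else None
        Y2 = comp["dec2"].forward(fused, norm).data if "dec2" in comp else None
        return Y1, Y2

    # -- checkpointing --------------------------------------------------------

    def _config_hash(self) -> str:
        blob = json.dumps(self.get_params(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str) -> None:
        """Serialize parameters and config to a single .npz checkpoint."""
        check_is_fitted(self, "embedding_")
        arrays = {}
        for name, c in self._components_.items():
            for i, p in enumerate(c.parameters()):
                arrays[f"{name}__{i}"] = p.data
        arrays["_config"] = np.frombuffer(
            json.dumps({"params": self.get_params(), "hash": self._config_hash(),
                        "input_dims": self._input_dims_}, default=str).encode(),
            dtype=np.uint8)
        np.savez(path, **arrays)

    def load_params(self, path: str, input_dims: tuple[int, int]) -> "SpaMI":
        """Restore component parameters from a checkpoint into this estimator."""
        data = np.load(path)
        meta = json.loads(bytes(data["_config"]))
        if meta["hash"] != self._config_hash():
            raise ValueError("checkpoint config hash does not match this estimator")
        rng = np.random.default_rng(self.random_state)
        self._components_ = self._build_components(*input_dims, rng)
        for name, c in self._components_.items():
            for i, p in enumerate(c.parameters()):
                p.data = data[f"{name}__{i}"].copy()
        self._input_dims_ = tuple(input_dims)
        return self
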
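"""Spatial neighbor graph shared by both modalities.

Each spot selects its ``r`` nearest neighbors by Euclidean distance on the
shared coordinates; the directed selection is symmetrized by union (an edge
exists if either endpoint selected the other), so degrees can exceed ``r``.
Both modalities use the same graph — only node features differ.  Negative
pairs for the contrastive objective come from a corrupted view: identical
topology, rows of the feature matrix permuted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialGraph",
    "CorruptedFeatures",
    "build_knn_graph",
    "normalize_adjacency",
    "corrupt_features",
]


@dataclass
class SpatialGraph:
    coords: np.ndarray
    r: int
    neighbor_lists: list[np.ndarray]          # directed kNN selections
    adjacency: sp.csr_matrix                  # symmetrized, zero diagonal
    adjacency_selfloop: sp.csr_matrix = field(repr=False, default=None)
    normalized: sp.csr_matrix = field(repr=False, default=None)

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def edges(self) -> set[tuple[int, int]]:
        rows, cols = self.adjacency.nonzero()
        return set(zip(rows.tolist(), cols.tolist()))

    def edge_hash(self) -> int:
        rows, cols = self.adjacency.nonzero()
        return hash((rows.tobytes(), cols.tobytes()))

    def to_edge_list(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array of 0-based indices."""
        rows, cols = sp.triu(self.adjacency, k=1).nonzero()
        return np.column_stack([rows, cols])


@dataclass
class CorruptedFeatures:
    """Row-permuted features for the corrupted (negative-pair) view."""

    values: np.ndarray
    permutation: np.ndarray
    seed: int


def build_knn_graph(coords: np.ndarray, r: int) -> SpatialGraph:
    """Symmetrized r-nearest-neighbor graph on 2D coordinates.

    Distance ties are broken by ascending spot index so construction is
    deterministic; duplicate coordinates are allowed.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if r < 1 or r >= n:
        raise ValueError(f"neighbor count r must satisfy 1 <= r < n_spots, got r={r}, n={n}")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    # lexsort on (index, distance): distance is the primary key, index breaks ties
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
    neighbor_lists = [order[i, :r].copy() for i in range(n)]
    rows = np.repeat(np.arange(n), r)
    cols = np.concatenate(neighbor_lists)
    A = sp.coo_matrix((np.ones(n * r), (rows, cols)), shape=(n, n)).tocsr()
    A = ((A + A.T) > 0).astype(float).tocsr()  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    graph = SpatialGraph(coords=coords, r=r, neighbor_lists=neighbor_lists, adjacency=A)
    graph.adjacency_selfloop = (A + sp.identity(n, format="csr")).tocsr()
    graph.normalized = normalize_adjacency(A)
    return graph


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric GCN normalization D^{-1/2} (A + I) D^{-1/2}.

    Self-loops guarantee every degree is at least one, so no division by
    zero can occur.
    """
    A = sp.csr_matrix(A)
    A_tilde = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ A_tilde @ d_inv_sqrt).tocsr()


def corrupt_features(X: np.ndarray, seed: int) -> CorruptedFeatures:
    """Permute feature rows uniformly at random; topology is untouched."""
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    return CorruptedFeatures(values=X[perm], permutation=perm, seed=seed)
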
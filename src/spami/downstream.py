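"""Downstream analysis: Leiden clustering, partition metrics, spatial
autocorrelation, and denoising through the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    homogeneity_score,
    normalized_mutual_info_score,
)
from sklearn.neighbors import kneighbors_graph

from .graph import SpatialGraph
from .preprocessing import FeatureMatrix

__all__ = [
    "ClusteringResult",
    "MetricReport",
    "cluster_leiden",
    "evaluate_clustering",
    "morans_i",
    "cluster_indicator_morans_i",
    "grid_rook_adjacency",
    "denoise",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    resolution: float
    n_clusters: int
    seed: int


@dataclass
class MetricReport:
    ari: float
    ami: float
    nmi: float
    homogeneity: float
    morans_i: np.ndarray | None = field(default=None)

    def as_dict(self) -> dict:
        d = {"ari": self.ari, "ami": self.ami, "nmi": self.nmi,
             "homogeneity": self.homogeneity}
        if self.morans_i is not None:
            d["morans_i"] = [float(v) for v in np.atleast_1d(self.morans_i)]
        return d


def _leiden_once(g: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def cluster_leiden(Z: np.ndarray, n_neighbors: int = 15, resolution: float = 1.0,
                   seed: int = 0, target_n_clusters: int | None = None,
                   max_bisection: int = 25) -> ClusteringResult:
    """Leiden partition of a kNN graph built on the embedding.

    When ``target_n_clusters`` is given, the resolution is searched by
    bisection; if the exact count is unreachable the partition with the
    nearest achievable count is returned.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("embedding contains non-finite values")
    n = Z.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more spots than n_neighbors={n_neighbors}, got {n}")
    A = kneighbors_graph(Z, n_neighbors=n_neighbors, mode="connectivity")
    A = ((A + A.T) > 0).astype(float)
    sources, targets = A.nonzero()
    mask = sources < targets
    g = ig.Graph(n=n, edges=list(zip(sources[mask].tolist(), targets[mask].tolist())))

    if target_n_clusters is None:
        labels = _leiden_once(g, resolution, seed)
        return ClusteringResult(labels=labels, resolution=resolution,
                                n_clusters=int(labels.max()) + 1, seed=seed)

    lo, hi = 1e-3, 5.0
    best: tuple[int, float, np.ndarray] | None = None

    def record(res: float) -> int:
        nonlocal best
        labels = _leiden_once(g, res, seed)
        k = int(labels.max()) + 1
        gap = abs(k - target_n_clusters)
        if best is None or gap < best[0]:
            best = (gap, res, labels)
        return k

    # expand the bracket until it straddles the target count
    while record(hi) < target_n_clusters and hi < 200:
        hi *= 2
    while record(lo) > target_n_clusters and lo > 1e-6:
        lo /= 2
    for _ in range(max_bisection):
        mid = 0.5 * (lo + hi)
        k = record(mid)
        if k == target_n_clusters:
            break
        if k < target_n_clusters:
            lo = mid
        else:
            hi = mid
    gap, res, labels = best
    return ClusteringResult(labels=labels, resolution=res,
                            n_clusters=int(labels.max()) + 1, seed=seed)


def evaluate_clustering(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """ARI, AMI, NMI and homogeneity between predicted and true partitions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    return MetricReport(
        ari=float(adjusted_rand_score(truth, pred)),
        ami=float(adjusted_mutual_info_score(truth, pred)),
        nmi=float(normalized_mutual_info_score(truth, pred)),
        homogeneity=float(homogeneity_score(truth, pred)),
    )


def grid_rook_adjacency(rows: int, cols: int) -> sp.csr_matrix:
    """Rook (4-neighbor) adjacency of a rows x cols grid, row-major order."""
    n = rows * cols
    r, c = np.divmod(np.arange(n), cols)
    pairs = []
    right = np.flatnonzero(c < cols - 1)
    pairs.append((right, right + 1))
    down = np.flatnonzero(r < rows - 1)
    pairs.append((down, down + cols))
    src = np.concatenate([p[0] for p in pairs])
    dst = np.concatenate([p[1] for p in pairs])
    A = sp.coo_matrix((np.ones(src.size), (src, dst)), shape=(n, n))
    A = A + A.T
    return A.tocsr()


def morans_i(values: np.ndarray, graph: SpatialGraph | sp.spmatrix,
             row_normalize: bool = True) -> np.ndarray:
    """Moran's I spatial autocorrelation, one score per column.

    I = (N / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values; with row-normalized weights S0 = N.  For cluster assessment,
    pass one-hot cluster indicator columns.
    """
    W = graph.adjacency if isinstance(graph, SpatialGraph) else sp.csr_matrix(graph)
    W = sp.csr_matrix(W, dtype=float)
    if row_normalize:
        deg = np.asarray(W.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        W = sp.diags(1.0 / deg) @ W
    X = np.asarray(values, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X.T).T if squeeze else X
    n = X.shape[0]
    if W.shape[0] != n:
        raise ValueError("weights and values disagree on spot count")
    Z = X - X.mean(axis=0, keepdims=True)
    denom = (Z**2).sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("Moran's I is undefined for constant input")
    s0 = W.sum()
    num = (Z * (W @ Z)).sum(axis=0)
    out = (n / s0) * num / denom
    return float(out[0]) if squeeze else out


def cluster_indicator_morans_i(labels: np.ndarray,
                               graph: SpatialGraph | sp.spmatrix) -> np.ndarray:
    """Moran's I of each cluster's one-hot indicator over the spatial graph."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    onehot = (labels[:, None] == classes[None, :]).astype(float)
    return morans_i(onehot, graph)


def umap_2d(Z: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2D UMAP projection of an embedding (visual convenience only)."""
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed, n_neighbors=n_neighbors)
    return reducer.fit_transform(np.asarray(Z, dtype=float))


def plot_spatial_domains(coords: np.ndarray, labels: np.ndarray, path: str,
                         title: str = "spatial domains") -> None:
    """Scatter of spots colored by cluster, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(coords[:, 1], -coords[:, 0], c=labels, cmap="tab10", s=14)
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def denoise(model, fm1: FeatureMatrix, fm2: FeatureMatrix) -> dict:
    """Back-project decoder outputs to feature space where a linear inverse exists.

    Returns per-modality dicts with ``values`` and ``in_feature_space``:
    PCA-reduced modalities are mapped back through the stored loadings and
    centering; CLR/LSI modalities are returned in their normalized/reduced
    space (no inverse to raw counts is defined) with the flag set False.
    """
    Y1, Y2 = model.decode()
    out = {}
    for key, Y, fm in (("modality1", Y1, fm1), ("modality2", Y2, fm2)):
        if Y is None:
            continue
        rmap = fm.reduction_map
        if rmap.invertible:
            out[key] = {"values": rmap.inverse(Y), "in_feature_space": True,
                        "feature_names": fm.feature_names}
        else:
            out[key] = {"values": Y, "in_feature_space": False,
                        "feature_names": fm.feature_names}
    return out
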
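"""Per-modality preprocessing into the reduced feature matrices X1, X2.

RNA: filter genes detected in fewer than ``min_cells`` spots, depth-normalize
to the median total count, log1p, select highly variable genes, PCA to
``d_out`` dimensions.  ADT protein tags: centered log-ratio (CLR) per spot.
ATAC peaks: drop peaks active in fewer than 0.5% of spots, TF-IDF weighting,
truncated SVD (LSI) to ``d_out``.  Each linear reduction stores its
back-projection so decoded embeddings can be returned to feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA, TruncatedSVD

__all__ = [
    "FeatureMatrix",
    "ReductionMap",
    "preprocess_rna",
    "clr_normalize",
    "lsi_reduce",
    "match_dims",
]


@dataclass
class ReductionMap:
    """Stored linear back-projection for a PCA/LSI reduction.

    ``inverse(Z) = Z @ components + mean`` maps reduced coordinates back to
    the (possibly feature-subset) input space.  ``invertible`` is False for
    transforms with no meaningful inverse to raw space (CLR, TF-IDF+SVD).
    """

    components: np.ndarray | None = None   # (d_out, n_features_kept)
    mean: np.ndarray | None = None
    kept_features: np.ndarray | None = None
    invertible: bool = False

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        if not self.invertible or self.components is None:
            raise ValueError("no back-projection is defined for this reduction")
        out = Z @ self.components
        if self.mean is not None:
            out = out + self.mean
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        if self.components is None:
            return np.asarray(X)
        Xc = X - self.mean if self.mean is not None else X
        return Xc @ self.components.T


@dataclass
class FeatureMatrix:
    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    reduction_map: ReductionMap = field(default_factory=ReductionMap)
    kind: str = "identity"  # "pca" | "clr" | "lsi" | "identity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _fix_component_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Force the largest-magnitude loading of each component positive (in place)."""
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0


def preprocess_rna(counts: np.ndarray, min_cells: int = 10, d_out: int = 50,
                   n_top_genes: int = 3000, feature_names: list[str] | None = None,
                   target_sum: float | None = None) -> FeatureMatrix:
    """Filter, normalize, log-transform and PCA-reduce an RNA count matrix.

    Depth normalization scales each spot to the median total count (scanpy's
    default when ``target_sum`` is None).  If fewer informative genes survive
    filtering than ``d_out``, the output dimensionality drops to the
    achievable rank.
    """
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    names = list(feature_names) if feature_names is not None else [f"gene_{i}" for i in range(g)]
    adata = AnnData(X=counts.copy())
    adata.var_names = names
    sc.pp.filter_genes(adata, min_cells=min_cells)
    if adata.n_vars == 0:
        raise ValueError(f"all genes are detected in fewer than {min_cells} spots")
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    if adata.n_vars > n_top_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top_genes, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    X = np.asarray(adata.X, dtype=float)
    d_eff = min(d_out, min(X.shape) - 1) if min(X.shape) > 1 else 1
    pca = PCA(n_components=d_eff, svd_solver="full")
    Z = pca.fit_transform(X)
    components = pca.components_.copy()
    _fix_component_signs(components, Z)
    kept = np.array([names.index(v) for v in adata.var_names])
    rmap = ReductionMap(components=components, mean=pca.mean_.copy(),
                        kept_features=kept, invertible=True)
    return FeatureMatrix(values=Z, feature_names=list(adata.var_names),
                         reduction_map=rmap, kind="pca")


def clr_normalize(counts: np.ndarray, pseudocount: float = 1.0,
                  feature_names: list[str] | None = None) -> FeatureMatrix:
    """Centered log-ratio transform per spot (row-wise margin).

    output[i, p] = ln((c[i,p]+pc) / geometric_mean_p(c[i,·]+pc)); each row
    sums to zero by construction.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("CLR input must be nonnegative")
    if pseudocount <= 0 and np.any(counts == 0):
        raise ValueError("pseudocount must be positive when zero counts are present")
    logc = np.log(counts + pseudocount)
    out = logc - logc.mean(axis=1, keepdims=True)
    names = list(feature_names) if feature_names is not None else [
        f"protein_{i}" for i in range(counts.shape[1])
    ]
    return FeatureMatrix(values=out, feature_names=names,
                         reduction_map=ReductionMap(invertible=False), kind="clr")


def lsi_reduce(peaks: np.ndarray, min_cell_frac: float = 0.005, d_out: int = 50,
               tfidf_scale: float = 1e4,
               feature_names: list[str] | None = None) -> FeatureMatrix:
    """TF-IDF weighting followed by truncated SVD (latent semantic indexing).

    Peaks active in fewer than ``ceil(min_cell_frac * n_spots)`` spots are
    removed first.  TF is the within-spot term frequency, IDF the inverse
    document frequency n_spots / peak_frequency, combined as
    ``log1p(TF * IDF * tfidf_scale)``.  The depth-correlated first component
    is retained.  Component signs are fixed by forcing the largest-magnitude
    loading positive.
    """
    peaks = np.asarray(peaks, dtype=float)
    if np.any(peaks < 0):
        raise ValueError("peak matrix must be nonnegative")
    n, k = peaks.shape
    names = list(feature_names) if feature_names is not None else [f"peak_{i}" for i in range(k)]
    min_cells = int(np.ceil(min_cell_frac * n))
    df = (peaks > 0).sum(axis=0)
    keep = df >= min_cells
    if not np.any(keep):
        raise ValueError("all peaks filtered out; lower min_cell_frac")
    X = peaks[:, keep]
    names = [nm for nm, kf in zip(names, keep) if kf]
    rowsum = X.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    tf = X / rowsum
    idf = n / (peaks > 0)[:, keep].sum(axis=0)
    mat = np.log1p(tf * idf[None, :] * tfidf_scale)
    if d_out > min(mat.shape) - 1:
        raise ValueError(
            f"d_out={d_out} exceeds achievable rank; at most {min(mat.shape) - 1} "
            "components are available after filtering"
        )
    svd = TruncatedSVD(n_components=d_out, random_state=0, algorithm="arpack")
    Z = svd.fit_transform(sp.csr_matrix(mat))
    components = svd.components_.copy()
    _fix_component_signs(components, Z)
    rmap = ReductionMap(components=components, mean=None,
                        kept_features=np.flatnonzero(keep), invertible=False)
    return FeatureMatrix(values=Z, feature_names=names, reduction_map=rmap, kind="lsi")


def match_dims(fm1: FeatureMatrix, fm2: FeatureMatrix,
               matched: bool = True) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Re-reduce the higher-dimensional matrix to min(d1, d2) when requested.

    Mirrors the convention of matching the RNA dimensionality to a low-plex
    protein panel (e.g. 21 retained proteins -> RNA re-reduced to 21).
    """
    if not matched or fm1.d == fm2.d:
        return fm1, fm2
    target = min(fm1.d, fm2.d)

    def shrink(fm: FeatureMatrix) -> FeatureMatrix:
        if fm.d <= target:
            return fm
        pca = PCA(n_components=target, svd_solver="full")
        Z = pca.fit_transform(fm.values)
        components = pca.components_.copy()
        _fix_component_signs(components, Z)
        # chain with any prior linear reduction: inverse goes through both
        if fm.reduction_map.invertible and fm.reduction_map.components is not None:
            chained = ReductionMap(
                components=components @ fm.reduction_map.components,
                mean=pca.mean_ @ fm.reduction_map.components + fm.reduction_map.mean,
                kept_features=fm.reduction_map.kept_features,
                invertible=True,
            )
        else:
            chained = ReductionMap(components=components, mean=pca.mean_.copy(),
                                   kept_features=None, invertible=False)
        return FeatureMatrix(values=Z, feature_names=[f"dim_{i}" for i in range(target)],
                             reduction_map=chained, kind=fm.kind)

    return shrink(fm1), shrink(fm2)
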
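"""Reading and writing paired datasets.

The primary interchange container is a single AnnData (.h5ad) file: X holds
the first modality, ``obsm["modality2"]`` the second, ``obsm["spatial"]``
the coordinates, ``obs["ground_truth"]`` optional labels.  A CSV mirror
(one file per matrix) and 10x-style MTX triplets are supported as
secondary formats.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData
import anndata

from .containers import SpatialOmicsPair

__all__ = ["pair_to_anndata", "anndata_to_pair", "write_pair", "read_pair",
           "write_pair_csv", "read_pair_csv"]


def pair_to_anndata(pair: SpatialOmicsPair) -> AnnData:
    names1, names2 = pair.feature_names or (
        [f"f1_{i}" for i in range(pair.X1.shape[1])],
        [f"f2_{i}" for i in range(pair.X2.shape[1])],
    )
    adata = AnnData(X=np.asarray(pair.X1, dtype=float))
    adata.var_names = names1
    adata.obs_names = [f"spot_{i}" for i in range(pair.n_spots)]
    adata.obsm["spatial"] = np.asarray(pair.coords, dtype=float)
    adata.obsm["modality2"] = np.asarray(pair.X2, dtype=float)
    adata.uns["modalities"] = list(pair.modalities)
    adata.uns["modality2_features"] = list(names2)
    if pair.labels is not None:
        adata.obs["ground_truth"] = pd.Categorical(pair.labels.astype(int))
    if pair.factor_activity is not None:
        adata.obsm["factor_activity"] = np.asarray(pair.factor_activity, dtype=float)
    for k, v in pair.meta.items():
        adata.uns[f"meta_{k}"] = list(v) if isinstance(v, tuple) else v
    return adata


def anndata_to_pair(adata: AnnData) -> SpatialOmicsPair:
    labels = None
    if "ground_truth" in adata.obs:
        labels = np.asarray(adata.obs["ground_truth"]).astype(int)
    X1 = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    meta = {k[5:]: v for k, v in adata.uns.items() if k.startswith("meta_")}
    return SpatialOmicsPair(
        X1=np.asarray(X1, dtype=float),
        X2=np.asarray(adata.obsm["modality2"], dtype=float),
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        modalities=tuple(adata.uns.get("modalities", ("rna", "adt"))),
        labels=labels,
        factor_activity=np.asarray(adata.obsm["factor_activity"])
        if "factor_activity" in adata.obsm else None,
        feature_names=(list(adata.var_names),
                       list(adata.uns.get("modality2_features",
                                          [f"f2_{i}" for i in range(adata.obsm["modality2"].shape[1])]))),
        meta=meta,
    )


def write_pair(pair: SpatialOmicsPair, path: str) -> None:
    pair_to_anndata(pair).write_h5ad(path)


def read_pair(path: str) -> SpatialOmicsPair:
    return anndata_to_pair(anndata.read_h5ad(path))


def write_pair_csv(pair: SpatialOmicsPair, outdir: str) -> None:
    """CSV mirror: one dense CSV per matrix plus coordinates and labels."""
    os.makedirs(outdir, exist_ok=True)
    names1, names2 = pair.feature_names or (None, None)
    pd.DataFrame(pair.X1, columns=names1).to_csv(os.path.join(outdir, "modality1.csv"), index=False)
    pd.DataFrame(pair.X2, columns=names2).to_csv(os.path.join(outdir, "modality2.csv"), index=False)
    pd.DataFrame(pair.coords, columns=["x", "y"]).to_csv(os.path.join(outdir, "coords.csv"), index=False)
    if pair.labels is not None:
        pd.DataFrame({"ground_truth": pair.labels}).to_csv(
            os.path.join(outdir, "labels.csv"), index=False)


def read_pair_csv(indir: str, modalities: tuple[str, str] = ("rna", "adt")) -> SpatialOmicsPair:
    m1 = pd.read_csv(os.path.join(indir, "modality1.csv"))
    m2 = pd.read_csv(os.path.join(indir, "modality2.csv"))
    coords = pd.read_csv(os.path.join(indir, "coords.csv")).to_numpy(dtype=float)
    labels_path = os.path.join(indir, "labels.csv")
    labels = (pd.read_csv(labels_path)["ground_truth"].to_numpy(dtype=int)
              if os.path.exists(labels_path) else None)
    return SpatialOmicsPair(
        X1=m1.to_numpy(dtype=float), X2=m2.to_numpy(dtype=float), coords=coords,
        modalities=modalities, labels=labels,
        feature_names=(list(m1.columns), list(m2.columns)),
    )


def read_mtx_matrix(prefix: str) -> tuple[np.ndarray, list[str]]:
    """Load a 10x-style triplet: <prefix>.mtx (features x spots),
    <prefix>.features.tsv, <prefix>.barcodes.tsv; returns spots x features."""
    mat = scipy.io.mmread(f"{prefix}.mtx")
    features = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None)[0].tolist()
    X = np.asarray(sp.csr_matrix(mat).todense()).T
    return X, features
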
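"""End-to-end pipeline driver with a reproducibility manifest.

A YAML config selects the stages (simulate or load, preprocess, graph,
train, cluster, evaluate, denoise) and their settings; every stage writes
its outputs into the run directory, and a single ``manifest.json`` records
the config snapshot, master seed, package version, input checksums and
per-stage timings.  Re-running an identical config reproduces identical
deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import default_config
from .containers import SpatialOmicsPair
from .downstream import (cluster_indicator_morans_i, cluster_leiden, denoise,
                         evaluate_clustering)
from .graph import build_knn_graph
from .io import read_pair, write_pair, write_pair_csv
from .preprocessing import clr_normalize, lsi_reduce, match_dims, preprocess_rna
from .simulate import SimulationConfig, simulate_pair
from .training import train

__all__ = ["run_pipeline", "load_pipeline_config"]

_KNOWN_STAGES = ("simulate", "load", "preprocess", "graph", "train",
                 "cluster", "evaluate", "denoise")


def load_pipeline_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    stages = cfg.get("stages")
    if not stages or not isinstance(stages, list):
        raise ValueError("config field 'stages' must be a non-empty list")
    for s in stages:
        if s not in _KNOWN_STAGES:
            raise ValueError(f"config field 'stages': unknown stage {s!r}; "
                             f"known stages: {_KNOWN_STAGES}")
    if "simulate" in stages and "load" in stages:
        raise ValueError("config: use either 'simulate' or 'load', not both")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("config field 'seed' must be an integer")


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _preprocess_pair(pair: SpatialOmicsPair, settings: dict):
    d_out = int(settings.get("d_out", 50))
    fm1 = preprocess_rna(pair.X1, min_cells=int(settings.get("min_cells", 10)),
                         d_out=d_out, feature_names=(pair.feature_names or (None, None))[0])
    second = pair.modalities[1]
    if second == "adt":
        fm2 = clr_normalize(pair.X2, feature_names=(pair.feature_names or (None, None))[1])
    else:
        fm2 = lsi_reduce(pair.X2, min_cell_frac=float(settings.get("min_cell_frac", 0.005)),
                         d_out=min(d_out, pair.X2.shape[1] - 1, pair.n_spots - 1),
                         feature_names=(pair.feature_names or (None, None))[1])
    if settings.get("match_dims", False):
        fm1, fm2 = match_dims(fm1, fm2)
    return fm1, fm2


def run_pipeline(config: str | dict, out_dir: str | None = None) -> str:
    """Execute the requested stages; returns the run directory path."""
    if isinstance(config, str):
        cfg = load_pipeline_config(config)
    else:
        _validate_config(config)
        cfg = config
    stages = cfg["stages"]
    seed = int(cfg.get("seed", 0))
    out_dir = out_dir or cfg.get("out", "spami_run")
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": cfg, "seed": seed, "version": __version__,
                "input_checksums": {}, "timings_s": {}}

    pair = fm1 = fm2 = graph = est = fusion = clusters = None
    dataset_path = os.path.join(out_dir, "dataset.h5ad")

    def timed(name, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        return result

    if "simulate" in stages:
        s = dict(cfg.get("simulate", {}))
        s.setdefault("seed", seed)
        if "grid" in s:
            s["grid_shape"] = tuple(s.pop("grid"))
        if "pair" in s:
            s["modality_pair"] = s.pop("pair")
        sim_cfg = SimulationConfig(**s)
        pair = timed("simulate", lambda: simulate_pair(sim_cfg))
        write_pair(pair, dataset_path)
        if cfg.get("csv_mirror"):
            write_pair_csv(pair, os.path.join(out_dir, "csv"))
    elif "load" in stages:
        src = cfg.get("load", {}).get("path")
        if not src or not os.path.exists(src):
            raise FileNotFoundError(f"config field 'load.path': missing input {src!r}")
        manifest["input_checksums"][src] = _checksum(src)
        pair = timed("load", lambda: read_pair(src))
        write_pair(pair, dataset_path)

    def need_pair():
        nonlocal pair
        if pair is None:
            if not os.path.exists(dataset_path):
                raise FileNotFoundError(
                    "missing upstream stage output: dataset.h5ad (run simulate/load first)")
            pair = read_pair(dataset_path)
        return pair

    if "preprocess" in stages:
        fm1, fm2 = timed("preprocess",
                         lambda: _preprocess_pair(need_pair(), cfg.get("preprocess", {})))
        np.savez(os.path.join(out_dir, "features.npz"),
                 X1=fm1.values, X2=fm2.values)

    if "graph" in stages or "train" in stages:
        tc = cfg.get("train", {})
        preset = tc.get("preset", "simulated")
        overrides = {k: v for k, v in tc.items() if k != "preset"}
        overrides.setdefault("seed", seed)
        train_cfg = default_config(preset, **overrides)
        graph = timed("graph", lambda: build_knn_graph(need_pair().coords,
                                                       train_cfg.neighbor_r))
        np.savetxt(os.path.join(out_dir, "edges.tsv"), graph.to_edge_list(),
                   fmt="%d", delimiter="\t")

    if "train" in stages:
        if fm1 is None:
            feats = os.path.join(out_dir, "features.npz")
            if not os.path.exists(feats):
                raise FileNotFoundError(
                    "missing upstream stage output: features.npz (run preprocess first)")
            data = np.load(feats)
            X1p, X2p = data["X1"], data["X2"]
        else:
            X1p, X2p = fm1.values, fm2.values
        p = need_pair()
        proc_pair = SpatialOmicsPair(X1=X1p, X2=X2p, coords=p.coords,
                                     modalities=p.modalities, labels=p.labels)
        est, fusion, history = timed("train", lambda: train(proc_pair, graph, train_cfg))
        pd.DataFrame(history).to_csv(os.path.join(out_dir, "loss_history.csv"),
                                     index_label="epoch")
        np.savez(os.path.join(out_dir, "embeddings.npz"), Z=fusion.Z,
                 alpha=fusion.alpha if fusion.alpha is not None else np.empty((0, 2)),
                 Z1=est.modality_embeddings_[0] if est.modality_embeddings_[0] is not None else np.empty(0),
                 Z2=est.modality_embeddings_[1] if est.modality_embeddings_[1] is not None else np.empty(0))
        est.save(os.path.join(out_dir, "checkpoint.npz"))

    def need_embedding():
        if fusion is not None:
            return fusion.Z
        emb = os.path.join(out_dir, "embeddings.npz")
        if not os.path.exists(emb):
            raise FileNotFoundError(
                "missing upstream stage output: embeddings.npz (run train first)")
        return np.load(emb)["Z"]

    if "cluster" in stages:
        cc = cfg.get("cluster", {})
        p = need_pair()
        target = cc.get("target_n_clusters")
        if target is None and cc.get("match_ground_truth", True) and p.labels is not None:
            target = int(len(np.unique(p.labels)))
        clusters = timed("cluster", lambda: cluster_leiden(
            need_embedding(), n_neighbors=int(cc.get("n_neighbors", 15)),
            resolution=float(cc.get("resolution", 1.0)), seed=seed,
            target_n_clusters=target))
        pd.DataFrame({"spot": np.arange(len(clusters.labels)),
                      "leiden": clusters.labels}).to_csv(
            os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
        if cc.get("plot", False):
            from .downstream import plot_spatial_domains
            plot_spatial_domains(p.coords, clusters.labels,
                                 os.path.join(out_dir, "domains.png"))

    if "evaluate" in stages:
        if clusters is None:
            cl_path = os.path.join(out_dir, "clusters.tsv")
            if not os.path.exists(cl_path):
                raise FileNotFoundError(
                    "missing upstream stage output: clusters.tsv (run cluster first)")
            labels_pred = pd.read_csv(cl_path, sep="\t")["leiden"].to_numpy()
        else:
            labels_pred = clusters.labels
        p = need_pair()
        if p.labels is None:
            raise ValueError("evaluate stage requires ground-truth labels")
        g = graph or build_knn_graph(p.coords, int(cfg.get("train", {}).get("neighbor_r", 3)))
        rep = timed("evaluate", lambda: evaluate_clustering(labels_pred, p.labels))
        rep.morans_i = cluster_indicator_morans_i(labels_pred, g)
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(rep.as_dict(), fh, indent=2)
        pd.DataFrame([rep.as_dict()]).drop(columns=["morans_i"], errors="ignore").to_csv(
            os.path.join(out_dir, "metrics.tsv"), sep="\t", index=False)

    if "denoise" in stages:
        if est is None or fm1 is None:
            raise ValueError("denoise stage requires preprocess and train in the same run")
        den = timed("denoise", lambda: denoise(est, fm1, fm2))
        np.savez(os.path.join(out_dir, "denoised.npz"),
                 **{k: v["values"] for k, v in den.items()})

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir
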
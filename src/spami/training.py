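"""Functional training surface and ablation studies.

Thin wrappers over the :class:`~spami.estimator.SpaMI` estimator: ``train``
runs one joint optimization and returns the fitted model, its fusion
result and the loss history; ``run_ablation`` retrains the full model and
each requested variant on identical data and seeds and tabulates the
clustering metrics against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TrainConfig
from .containers import SpatialOmicsPair
from .downstream import cluster_leiden, evaluate_clustering
from .estimator import SpaMI
from .graph import SpatialGraph
from .model import FusionResult

__all__ = ["train", "run_ablation", "estimator_from_config"]


def estimator_from_config(cfg: TrainConfig, seed: int | None = None) -> SpaMI:
    return SpaMI(
        hidden_dim=cfg.hidden_dim,
        latent_dim=cfg.latent_dim,
        attention_hidden_dim=cfg.attention_hidden_dim,
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        neighbor_r=cfg.neighbor_r,
        loss_weights=cfg.loss_weights,
        single_modality_mode=cfg.single_modality_mode,
        ablation=cfg.ablation,
        random_state=cfg.seed if seed is None else seed,
    )


def train(pair: SpatialOmicsPair, graph: SpatialGraph | None = None,
          cfg: TrainConfig | None = None) -> tuple[SpaMI, FusionResult, dict]:
    """Joint full-batch optimization under the combined loss.

    Returns the fitted estimator, the eval-mode fusion result, and the
    per-epoch loss history (one list per component plus the total).
    """
    cfg = cfg or TrainConfig()
    est = estimator_from_config(cfg)
    est.fit(pair, graph=graph)
    fusion = FusionResult(Z=est.embedding_, alpha=est.attention_weights_)
    return est, fusion, est.loss_history_


ABLATION_VARIANTS = ("no_cosine", "no_contrastive", "concat_fusion")


def run_ablation(pair: SpatialOmicsPair, graph: SpatialGraph | None,
                 cfg_base: TrainConfig, variants: list[str] | None = None,
                 seeds: list[int] | None = None,
                 n_clusters: int | None = None) -> pd.DataFrame:
    """Train the full model and each ablation on identical data/seed grids.

    Requires ground-truth labels on ``pair``.  Returns one row per
    (variant, seed) with ARI/AMI/NMI/homogeneity of the Leiden partition
    (searched to the ground-truth cluster count) and the embedding width.
    """
    if pair.labels is None:
        raise ValueError("run_ablation requires ground-truth labels")
    variants = list(ABLATION_VARIANTS) if variants is None else list(variants)
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {v!r}; "
                             f"choose from {ABLATION_VARIANTS}")
    seeds = [cfg_base.seed] if seeds is None else list(seeds)
    if n_clusters is None:
        n_clusters = int(len(np.unique(pair.labels)))

    rows = []
    for variant in ["full"] + variants:
        for seed in seeds:
            cfg = TrainConfig(**{**cfg_base.to_dict(),
                                 "ablation": "none" if variant == "full" else variant,
                                 "seed": seed})
            est, fusion, _ = train(pair, graph, cfg)
            res = cluster_leiden(fusion.Z, seed=seed, target_n_clusters=n_clusters)
            rep = evaluate_clustering(res.labels, pair.labels)
            rows.append({
                "variant": variant, "seed": seed,
                "embedding_dim": fusion.Z.shape[1],
                "n_clusters": res.n_clusters,
                **rep.as_dict(),
            })
    return pd.DataFrame(rows)
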
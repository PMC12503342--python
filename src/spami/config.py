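"""Training configuration, per-dataset presets, and YAML (de)serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .model import LossWeights

__all__ = ["TrainConfig", "PRESETS", "default_config"]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``single_modality_mode`` restricts the model to one modality (no
    attention, no correspondence term); ``ablation`` removes one component
    for component-contribution studies.
    """

    learning_rate: float = 0.001
    epochs: int = 1000
    neighbor_r: int = 3
    loss_weights: LossWeights = field(default_factory=LossWeights)
    hidden_dim: int = 256
    latent_dim: int = 64
    attention_hidden_dim: int = 32
    dropout: float = 0.15
    seed: int = 0
    single_modality_mode: str = "off"       # off | modality1 | modality2
    ablation: str = "none"                  # none | no_cosine | no_contrastive | concat_fusion

    def __post_init__(self) -> None:
        if isinstance(self.loss_weights, (list, tuple)):
            self.loss_weights = LossWeights.from_list(self.loss_weights)
        elif isinstance(self.loss_weights, dict):
            self.loss_weights = LossWeights(**self.loss_weights)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be a positive integer")
        if self.neighbor_r < 1:
            raise ValueError("neighbor_r must be a positive integer")
        if self.single_modality_mode not in ("off", "modality1", "modality2"):
            raise ValueError(
                "single_modality_mode must be one of off|modality1|modality2, "
                f"got {self.single_modality_mode!r}"
            )
        if self.ablation not in ("none", "no_cosine", "no_contrastive", "concat_fusion"):
            raise ValueError(
                "ablation must be one of none|no_cosine|no_contrastive|concat_fusion, "
                f"got {self.ablation!r}"
            )

    # -- YAML round-trip ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loss_weights"] = self.loss_weights.as_list()
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TrainConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(text))


# Per-dataset presets: (lr, epochs, r, [gamma1, gamma2, lambda1, lambda2, mu]).
# "simulated" is the global default.
PRESETS: dict[str, dict] = {
    "simulated": dict(learning_rate=0.001, epochs=1000, neighbor_r=3,
                      loss_weights=[1, 1, 10, 10, 5]),
    "misar": dict(learning_rate=0.01, epochs=800, neighbor_r=3,
                  loss_weights=[1, 1, 10, 15, 3]),
    "atac_rna": dict(learning_rate=0.001, epochs=400, neighbor_r=6,
                     loss_weights=[1, 1, 10, 15, 5]),
    "stereo_cite": dict(learning_rate=0.0001, epochs=600, neighbor_r=3,
                        loss_weights=[1, 5, 10, 25, 1]),
}


def default_config(preset: str = "simulated", **overrides) -> TrainConfig:
    """Return the named hyperparameter preset as a TrainConfig."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available presets: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[preset])
    params.update(overrides)
    return TrainConfig(**params)
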
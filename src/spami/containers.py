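"""Shared in-memory containers for paired spatial omics data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpatialOmicsPair:
    """Two feature matrices over the same spots, with shared 2D coordinates.

    Attributes
    ----------
    X1, X2 : ndarray, shape (n_spots, d_j)
        Per-spot feature matrices of the two modalities (counts when raw,
        reduced features after preprocessing).
    coords : ndarray, shape (n_spots, 2)
        Spatial coordinates (x, y) shared by both modalities.
    modalities : tuple of str
        Modality names, e.g. ``("rna", "adt")`` or ``("rna", "atac")``.
    labels : ndarray or None
        Optional ground-truth domain labels (integers, 0 = background).
    factor_activity : ndarray or None
        Optional (n_spots, n_factors) ground-truth factor fields.
    feature_names : tuple of lists
        Feature identifiers per modality.
    """

    X1: np.ndarray
    X2: np.ndarray
    coords: np.ndarray
    modalities: tuple[str, str] = ("rna", "adt")
    labels: np.ndarray | None = None
    factor_activity: np.ndarray | None = None
    feature_names: tuple[list[str], list[str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.coords.shape[0]
        if self.X1.shape[0] != n or self.X2.shape[0] != n:
            raise ValueError(
                f"modalities and coordinates disagree on spot count: "
                f"{self.X1.shape[0]}, {self.X2.shape[0]}, {n}"
            )
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_spots, 2) array")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length must equal spot count")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]
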
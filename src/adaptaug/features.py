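"""12-dimensional state extraction from leaf and rust masks.

A state element holds, for the leaf region and for the rust region, the
normalized centroid (x, y), the area fraction and the mean RGB colour —
six numbers each, twelve in total, all in [0, 1].  An empty region maps to
all zeros.  Masks come either from the item's own ground-truth labels
("oracle" mode) or from trained leaf/rust identifier models ("identifier"
mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ImageVector, LabeledImage

__all__ = [
    "FEATURE_NAMES",
    "StateElement",
    "MaskSource",
    "region_features",
    "extract_state",
    "extract_state_vector",
    "states_to_frame",
]

FEATURE_NAMES = (
    "x_l", "y_l", "A_l", "R_l", "G_l", "B_l",
    "x_r", "y_r", "A_r", "R_r", "G_r", "B_r",
)


@dataclass(frozen=True)
class StateElement:
    """The 12 geometric/pixel indicators of one image, each in [0, 1]."""

    x_l: float
    y_l: float
    A_l: float
    R_l: float
    G_l: float
    B_l: float
    x_r: float
    y_r: float
    A_r: float
    R_r: float
    G_r: float
    B_r: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StateElement":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (12,):
            raise ValueError(f"state element needs 12 components, got {arr.shape}")
        return cls(**dict(zip(FEATURE_NAMES, arr.tolist())))


@dataclass(frozen=True)
class MaskSource:
    """Where state-feature masks come from.

    ``oracle`` uses each item's own ground-truth labels; ``identifier`` runs
    the two segmentation models (a leaf identifier and a rust identifier)
    on the image and uses their predictions.
    """

    mode: str = "oracle"
    leaf_identifier: object | None = None
    rust_identifier: object | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "identifier"):
            raise ValueError(f"unknown mask source mode {self.mode!r}")
        if self.mode == "identifier" and (
                self.leaf_identifier is None or self.rust_identifier is None):
            raise ValueError("identifier mode requires both identifier models")


def region_features(image: np.ndarray, mask: np.ndarray
                    ) -> tuple[float, float, float, float, float, float]:
    """(x, y, A, R, G, B) of one masked region, normalized to [0, 1].

    x and y are the centroid column/row divided by (W-1)/(H-1); A is the
    mask pixel count over H*W; R, G, B are the per-channel means over the
    mask divided by 255.  Empty mask -> all zeros.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} dimensions differ")
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    if rows.size == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    x = float(cols.mean() / (w - 1)) if w > 1 else 0.5
    y = float(rows.mean() / (h - 1)) if h > 1 else 0.5
    area = float(rows.size / (h * w))
    rgb = image[rows, cols].astype(float).mean(axis=0) / 255.0
    return (x, y, area, float(rgb[0]), float(rgb[1]), float(rgb[2]))


def _masks_for(item: LabeledImage, source: MaskSource
               ) -> tuple[np.ndarray, np.ndarray]:
    if source.mode == "oracle":
        return item.leaf_label, item.rust_label
    from .segbackend import predict  # local import avoids a cycle
    return (predict(source.leaf_identifier, item.image),
            predict(source.rust_identifier, item.image))


def extract_state(item: LabeledImage,
                  source: MaskSource = MaskSource()) -> StateElement:
    """Extract the 12-feature state of one image."""
    leaf_mask, rust_mask = _masks_for(item, source)
    leaf = region_features(item.image, leaf_mask)
    rust = region_features(item.image, rust_mask)
    return StateElement(*leaf, *rust)


def extract_state_vector(vec: ImageVector,
                         source: MaskSource = MaskSource()
                         ) -> tuple[StateElement, ...]:
    """Per-image states aligned with the image vector, order preserved."""
    if len(vec) == 0:
        raise ValueError("cannot extract a state vector from an empty image vector")
    return tuple(extract_state(item, source) for item in vec)


def states_to_frame(ids: Sequence[str],
                    states: Sequence[StateElement]) -> pd.DataFrame:
    """One row per image: id + the 12 named feature columns in fixed order."""
    if len(ids) != len(states):
        raise ValueError("ids and states must align")
    data = {"id": list(ids)}
    arrs = np.array([s.to_array() for s in states])
    for j, name in enumerate(FEATURE_NAMES):
        data[name] = arrs[:, j]
    return pd.DataFrame(data)
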
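"""Core data containers shared across the pipeline.

Conventions: images are 2-D arrays indexed (row, col), 0-based; physical
positions are measured in mm from the top-left corner of a tile or mosaic;
areas are reported both in pixels and in um^2 via the pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageTile",
    "LabelMask",
    "ConfusionCounts",
    "CellRegion",
    "MetricReport",
]


@dataclass
class ImageTile:
    """A single grayscale fluorescence tile with pixel calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative intensity array (height x width).
    bit_depth : int
        8 or 16; intensities must lie within ``[0, 2**bit_depth - 1]``.
    um_per_px : float
        Physical size of one pixel edge in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"tile must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        lo, hi = self.pixels.min() if self.pixels.size else 0, self.pixels.max() if self.pixels.size else 0
        if self.pixels.size and (lo < 0 or hi > 2**self.bit_depth - 1):
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * (self.um_per_px / 1000.0) ** 2


def as_label_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce an array to a boolean label mask, validating binarity."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    allowed = {0, 1, 255}
    if not set(vals.tolist()) <= allowed:
        raise ValueError(f"mask is not binary; values {vals[:8]}")
    return mask > 0


# A LabelMask is simply a boolean ndarray co-registered with a tile; the
# helper above is the single point of coercion/validation.
LabelMask = np.ndarray


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts for one prediction/ground-truth pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CellRegion:
    """One segmented goblet cell (an 8-connected component).

    ``area_um2 = area_px * um_per_px**2``; eccentricity is that of the
    ellipse with matching second central moments, 0 for a circle and for
    single-pixel regions.
    """

    label: int
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    eccentricity: float
    cluster_id: int = -1
    pixels: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MetricReport:
    """Pixel-level segmentation metrics derived from confusion counts."""

    dice: float
    iou: float
    recall: float
    precision: float
    fpr: float
    ap: float | None = None
    degenerate: bool = False  # flags empty-vs-empty convention use

    def as_dict(self) -> dict:
        d = {
            "dice": self.dice,
            "iou": self.iou,
            "recall": self.recall,
            "precision": self.precision,
            "fpr": self.fpr,
        }
        if self.ap is not None:
            d["ap"] = self.ap
        return d
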
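"""Semi-automated ground-truth bootstrap.

The labeling pipeline starts from sectional adaptive thresholding (the
image is partitioned into rectangular sections, each with its own
intensity threshold, to cope with spatially varying background under
vessel shadows), then a baseline U-Net trained on those initial masks
produces rough predictions for subsequent manual refinement. Manual
refinement itself is a human step; this module only reads and writes
editable 0/255 mask PNGs and JSON section-grid sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .types import ImageTile
from .training import predict_prob

__all__ = ["SectionGrid", "sectional_threshold", "auto_section_thresholds",
           "bootstrap_predict"]


@dataclass
class SectionGrid:
    """Rectangular partition of a tile with per-section thresholds.

    ``row_edges``/``col_edges`` are monotone pixel boundaries starting at 0
    and ending at the image height/width; ``thresholds`` has shape
    ``(len(row_edges)-1, len(col_edges)-1)``.
    """

    row_edges: list[int]
    col_edges: list[int]
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        nr, nc = len(self.row_edges) - 1, len(self.col_edges) - 1
        if self.thresholds.shape != (nr, nc):
            raise ValueError(
                f"thresholds shape {self.thresholds.shape} != sections ({nr},{nc})"
            )
        for edges in (self.row_edges, self.col_edges):
            if edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("section edges must be strictly increasing from 0")

    def to_json(self) -> str:
        return json.dumps({"row_edges": list(map(int, self.row_edges)),
                           "col_edges": list(map(int, self.col_edges)),
                           "thresholds": self.thresholds.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "SectionGrid":
        d = json.loads(text)
        return cls(d["row_edges"], d["col_edges"], np.asarray(d["thresholds"]))


def sectional_threshold(tile: ImageTile, grid: SectionGrid) -> np.ndarray:
    """Binary mask: pixel is foreground iff intensity > its section threshold.

    Raising any section's threshold can only remove foreground pixels.
    """
    h, w = tile.shape
    if grid.row_edges[-1] != h or grid.col_edges[-1] != w:
        raise ValueError(
            f"section bounds {grid.row_edges[-1]}x{grid.col_edges[-1]} "
            f"do not match image {h}x{w}"
        )
    mask = np.zeros((h, w), dtype=bool)
    for i in range(len(grid.row_edges) - 1):
        r0, r1 = grid.row_edges[i], grid.row_edges[i + 1]
        for j in range(len(grid.col_edges) - 1):
            c0, c1 = grid.col_edges[j], grid.col_edges[j + 1]
            mask[r0:r1, c0:c1] = tile.pixels[r0:r1, c0:c1] > grid.thresholds[i, j]
    return mask


def auto_section_thresholds(tile: ImageTile,
                            grid_dims: tuple[int, int] = (4, 4)) -> SectionGrid:
    """Per-section Otsu thresholds — a reproducible automated surrogate
    for the manual per-section threshold choice.

    A constant section gets its own value as threshold (strict ``>`` then
    yields no foreground there).
    """
    nr, nc = grid_dims
    if nr < 1 or nc < 1:
        raise ValueError("grid dims must be >= 1")
    h, w = tile.shape
    row_edges = [round(i * h / nr) for i in range(nr + 1)]
    col_edges = [round(j * w / nc) for j in range(nc + 1)]
    th = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            sec = tile.pixels[row_edges[i]:row_edges[i + 1],
                              col_edges[j]:col_edges[j + 1]]
            if np.ptp(sec) == 0:
                th[i, j] = float(sec.flat[0]) if sec.size else 0.0
            else:
                th[i, j] = float(threshold_otsu(sec))
    return SectionGrid(row_edges, col_edges, th)


def bootstrap_predict(model, tiles: list[ImageTile],
                      threshold: float = 0.5) -> list[np.ndarray]:
    """Rough masks from a trained baseline model: binarized probabilities.

    ``model`` is any trained network with the standard tile-in/probability-
    map-out contract; masks equal ``p > threshold`` pixelwise.
    """
    masks = []
    for t in tiles:
        img = t.pixels.astype(np.float64) / (2**t.bit_depth - 1)
        masks.append(predict_prob(model, img) > threshold)
    return masks
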
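"""Downstream goblet-cell morphometry.

From a binarized probability map, cells are 8-connected components;
touching cells therefore merge into one region, which reproduces the
systematic undercount of aggregated cells relative to truth. Each region
carries centroid, pixel and physical area (``area_um2 = area_px *
um_per_px**2``) and the eccentricity of its moment-matched ellipse.
Densities are component counts per field area in cells/mm^2; mosaics of
tiles with a physical pitch yield spatial density maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .types import CellRegion, as_label_mask

__all__ = ["binarize", "extract_regions", "density", "DensityMap",
           "density_map", "density_agreement", "compare_timepoints",
           "moment_eccentricity"]


def moment_eccentricity(ys: np.ndarray, xs: np.ndarray) -> float:
    """Eccentricity of the moment-matched ellipse of a pixel set.

    Second central moments are computed over the union of unit pixel
    squares (the per-pixel 1/12 term), which removes most of the
    discretization bias for small regions; degenerate sets give 0.
    """
    if ys.size < 2:
        return 0.0
    dy = ys - ys.mean()
    dx = xs - xs.mean()
    mu20 = (dy * dy).mean() + 1 / 12
    mu02 = (dx * dx).mean() + 1 / 12
    mu11 = (dy * dx).mean()
    tr, det = mu20 + mu02, mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4 - det, 0.0)
    lam1 = tr / 2 + np.sqrt(disc)
    lam2 = tr / 2 - np.sqrt(disc)
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground iff p > threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    prob = np.asarray(prob, dtype=np.float64)
    return prob > threshold


def extract_regions(mask: np.ndarray, um_per_px: float = 1.0,
                    min_area_px: int = 5) -> list[CellRegion]:
    """8-connected components with morphometry.

    Regions below ``min_area_px`` pixels are dropped (single-pixel noise
    suppression; pass 0 to disable). Eccentricity comes from the
    second-central-moment ellipse, 0 for degenerate (line/point) regions.
    """
    m = as_label_mask(mask)
    labeled = measure.label(m, connectivity=2)
    regions = []
    for rp in measure.regionprops(labeled):
        if rp.area < max(min_area_px, 1):
            continue
        regions.append(
            CellRegion(
                label=int(rp.label),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=int(rp.area),
                area_um2=float(rp.area) * um_per_px**2,
                eccentricity=moment_eccentricity(rp.coords[:, 0], rp.coords[:, 1]),
                pixels=rp.coords,
            )
        )
    return regions


def density(regions: list[CellRegion], field_area_mm2: float) -> float:
    """Cell count per unit area, cells/mm^2."""
    if field_area_mm2 <= 0:
        raise ValueError("field_area_mm2 must be positive")
    return len(regions) / field_area_mm2


@dataclass
class DensityMap:
    """Per-tile densities on a physical grid (positions from top-left, mm)."""

    values: np.ndarray                      # (rows, cols), cells/mm^2; NaN = gap
    spacing_mm: float
    colormap: str = "viridis"
    bounds: tuple[float, float] | None = None
    tile_ids: dict = field(default_factory=dict)

    @property
    def positions_mm(self) -> np.ndarray:
        r, c = np.mgrid[0:self.values.shape[0], 0:self.values.shape[1]]
        return np.stack([r * self.spacing_mm, c * self.spacing_mm], axis=-1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (r, c), v in np.ndenumerate(self.values):
            rows.append({"row": r, "col": c,
                         "y_mm": r * self.spacing_mm, "x_mm": c * self.spacing_mm,
                         "density_cells_per_mm2": v,
                         "tile": self.tile_ids.get((r, c), "")})
        return pd.DataFrame(rows)

    def render(self, path, background: np.ndarray | None = None) -> None:
        """Write a colormap overlay PNG of the density grid."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        vmin, vmax = self.bounds if self.bounds else (None, None)
        extent = None
        if background is not None:
            extent = [0, self.values.shape[1] * self.spacing_mm,
                      self.values.shape[0] * self.spacing_mm, 0]
            ax.imshow(background, cmap="gray", extent=extent)
        im = ax.imshow(self.values, cmap=self.colormap, vmin=vmin, vmax=vmax,
                       alpha=0.7 if background is not None else 1.0,
                       extent=extent)
        fig.colorbar(im, ax=ax, label="GC density (cells/mm$^2$)")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def density_map(tile_regions: dict, layout: dict) -> DensityMap:
    """Assemble a DensityMap from per-tile region lists.

    ``tile_regions`` maps grid position ``(row, col)`` to a list of regions
    (or None for a missing tile, recorded as a NaN gap); ``layout`` needs
    ``grid_rows``, ``grid_cols``, ``spacing_mm`` and ``tile_area_mm2``.
    """
    rows, cols = layout["grid_rows"], layout["grid_cols"]
    area = layout["tile_area_mm2"]
    values = np.full((rows, cols), np.nan)
    for (r, c), regions in tile_regions.items():
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"tile position {(r, c)} outside grid")
        if regions is None:
            continue
        values[r, c] = density(regions, area)
    return DensityMap(values=values, spacing_mm=float(layout["spacing_mm"]))


def density_agreement(auto: np.ndarray, manual: np.ndarray):
    """Agreement of automated vs reference densities.

    Returns ``(r, ratio_mean, (lo, hi))``: the Pearson correlation, the
    mean of auto/manual ratios, and the 2.5th/97.5th percentiles of the
    relative error ``(auto - manual)/manual`` (the band that contains 95%
    of estimates).
    """
    a = np.asarray(auto, dtype=np.float64)
    m = np.asarray(manual, dtype=np.float64)
    if a.shape != m.shape or a.size < 3:
        raise ValueError("need paired lists with n >= 3")
    if np.ptp(a) == 0 or np.ptp(m) == 0:
        if np.allclose(a, m):
            return 1.0, 1.0, (0.0, 0.0)
        raise ValueError("zero-variance input")
    if np.any(m <= 0):
        raise ValueError("reference densities must be positive")
    r = float(np.corrcoef(a, m)[0, 1])
    ratio = a / m
    rel = ratio - 1.0
    lo, hi = np.percentile(rel, [2.5, 97.5])
    return r, float(ratio.mean()), (float(lo), float(hi))


def compare_timepoints(groups: dict):
    """Per-timepoint density and size summaries.

    ``groups`` maps a group label to a list of ``(regions, field_area_mm2)``
    tuples (one per analyzed tile). Returns a DataFrame with mean +/- sd of
    per-tile density and of pooled cell area for each group; sd is NaN when
    only one value exists, and empty groups are flagged in the ``note``
    column.
    """
    rows = []
    for name, tiles in groups.items():
        densities = [density(regs, area) for regs, area in tiles]
        areas = [reg.area_um2 for regs, _ in tiles for reg in regs]
        note = ""
        if not tiles or not areas:
            note = "empty group"
        rows.append({
            "group": name,
            "n_tiles": len(tiles),
            "n_cells": len(areas),
            "density_mean": float(np.mean(densities)) if densities else np.nan,
            "density_sd": float(np.std(densities, ddof=1)) if len(densities) > 1 else np.nan,
            "area_um2_mean": float(np.mean(areas)) if areas else np.nan,
            "area_um2_sd": float(np.std(areas, ddof=1)) if len(areas) > 1 else np.nan,
            "note": note,
        })
    return pd.DataFrame(rows)
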
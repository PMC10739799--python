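"""Synthetic fluorescence-microscopy scene generator with exact ground truth.

Emulates the statistics of moxifloxacin-stained conjunctival goblet-cell
images: bright roundish cells of a few tens of um^2, distributed individually
and in touching clusters at densities of order 1000-2400 cells/mm^2, over a
smoothly varying background shadowed by dark vessel-like structures, with
additive noise and occasional small bright non-cell artifacts.

Every scene carries generator truth: a label image assigning each foreground
pixel to exactly one cell, per-cell morphometry, and the exact density.
Generation is driven by a single ``numpy`` Generator seeded from
``SceneParams.seed`` and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .analysis import moment_eccentricity
from .types import CellRegion, ImageTile

__all__ = ["SceneParams", "Scene", "Mosaic", "generate_scene", "generate_mosaic"]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    Densities are in cells/mm^2, areas in um^2, intensities on a normalized
    [0, 1] scale before quantization to 16 bits.
    """

    width_px: int = 256
    height_px: int = 256
    um_per_px: float = 1.0
    target_density: float = 1500.0
    cell_area_mean: float = 60.0
    cell_area_sd: float = 15.0
    cell_ecc_range: tuple[float, float] = (0.3, 0.8)
    cluster_prob: float = 0.15
    vessel_count: int = 3
    vessel_shadow_depth: float = 0.5
    artifact_rate: float = 20.0
    noise_sd: float = 0.02
    background_gradient_amp: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.target_density < 0:
            raise ValueError("target_density must be >= 0")
        if self.cell_area_mean <= 0 or self.cell_area_sd <= 0:
            raise ValueError("cell area parameters must be positive")
        lo, hi = self.cell_ecc_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("cell_ecc_range must be an interval in [0, 1)")
        for name in ("cluster_prob", "vessel_shadow_depth"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.vessel_count < 0 or self.artifact_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.background_gradient_amp < 0:
            raise ValueError("background_gradient_amp must be >= 0")

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.um_per_px / 1000.0) ** 2


@dataclass
class Scene:
    """A generated tile plus its exact ground truth."""

    image: ImageTile
    mask: np.ndarray                 # bool, union of region pixel sets
    regions: list[CellRegion]
    true_density: float              # cells/mm^2, = len(regions)/area
    labels: np.ndarray = field(repr=False, default=None)  # int32 owner map, -1 background
    params: SceneParams | None = None


@dataclass
class Mosaic:
    """Grid of scenes with physical layout (tile pitch in mm)."""

    grid_rows: int
    grid_cols: int
    spacing_mm: float
    tiles: dict  # (row, col) -> Scene

    def items(self):
        return sorted(self.tiles.items())


def _sample_cell_geometry(rng: np.random.Generator, p: SceneParams) -> tuple[float, float, float]:
    """Semi-axes (a, b) in px and orientation for one cell."""
    min_area_px = 4.0
    area_px = 0.0
    for _ in range(100):
        area_um2 = rng.normal(p.cell_area_mean, p.cell_area_sd)
        area_px = area_um2 / p.um_per_px**2
        if area_px >= min_area_px:
            break
    else:  # pathological parameters; clamp
        area_px = min_area_px
    ecc = rng.uniform(*p.cell_ecc_range)
    ratio = np.sqrt(1.0 - ecc**2)          # b/a
    ab = area_px / np.pi
    a = np.sqrt(ab / ratio)
    b = ab / a
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def _raster_ellipse(cy: float, cx: float, a: float, b: float, theta: float,
                    shape: tuple[int, int], dilate: float = 0.0):
    """Pixel coordinates around the ellipse with normalized radius^2.

    Returns ``(yy, xx, r2, r2d)`` where ``r2`` uses semi-axes (a, b) and
    ``r2d`` uses the ellipse dilated additively by ``dilate`` pixels.
    """
    h, w = shape
    r = int(np.ceil(max(a, b) + dilate)) + 3
    r0, r1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    c0, c1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r2 = (u / a) ** 2 + (v / b) ** 2
    r2d = (u / (a + dilate)) ** 2 + (v / (b + dilate)) ** 2 if dilate else r2
    return yy, xx, r2, r2d


def _paint_background(rng: np.random.Generator, p: SceneParams) -> np.ndarray:
    h, w = p.height_px, p.width_px
    bg = np.full((h, w), 0.18)
    if p.background_gradient_amp > 0:
        coarse = rng.uniform(-1.0, 1.0, size=(4, 4))
        fieldv = ndimage.zoom(coarse, (h / 4, w / 4), order=3, mode="nearest")
        fieldv = fieldv[:h, :w]
        bg += p.background_gradient_amp * fieldv
    return np.clip(bg, 0.02, None)


def _vessel_shading(rng: np.random.Generator, p: SceneParams) -> np.ndarray:
    """Multiplicative shading field in (0, 1]; 1 where no vessel."""
    h, w = p.height_px, p.width_px
    if p.vessel_count == 0 or p.vessel_shadow_depth == 0:
        return np.ones((h, w))
    canvas = np.zeros((h, w))
    for _ in range(p.vessel_count):
        # random smooth walk across the field
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        width_v = rng.uniform(0.015, 0.045) * max(h, w)
        n_steps = int(2.0 * max(h, w) / 3)
        pts_y, pts_x = [], []
        for _ in range(n_steps):
            y += 3.0 * np.sin(theta)
            x += 3.0 * np.cos(theta)
            theta += rng.normal(0.0, 0.15)
            pts_y.append(y)
            pts_x.append(x)
        iy = np.clip(np.round(pts_y).astype(int), -1, h)
        ix = np.clip(np.round(pts_x).astype(int), -1, w)
        keep = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
        trail = np.zeros((h, w))
        trail[iy[keep], ix[keep]] = 1.0
        trail = ndimage.gaussian_filter(trail, sigma=width_v)
        if trail.max() > 0:
            canvas = np.maximum(canvas, trail / trail.max())
    return 1.0 - p.vessel_shadow_depth * canvas


def generate_scene(params: SceneParams) -> Scene:
    """Generate one scene with exact ground truth.

    The realized cell count is Poisson with mean ``target_density * area``;
    with probability ``cluster_prob`` a placement event spawns a cluster of
    2-4 mutually touching cells (counted individually in the truth). Cells
    are rendered as rotated ellipses with a Gaussian-ish radial intensity
    profile added on top of the background, so cells are always brighter
    than their local surroundings. Vessel shadows only darken the
    background; artifacts are bright but excluded from the mask.

    Raises
    ------
    ValueError
        If the mean cell area is below one pixel at the given calibration
        (degenerate geometry).
    """
    p = params
    if p.cell_area_mean / p.um_per_px**2 < 1.0:
        raise ValueError(
            "degenerate geometry: mean cell area "
            f"{p.cell_area_mean} um^2 is below 1 px^2 at {p.um_per_px} um/px"
        )
    rng = np.random.default_rng(p.seed)
    h, w = p.height_px, p.width_px

    bg = _paint_background(rng, p)
    bg *= _vessel_shading(rng, p)
    img = bg.copy()

    owner = np.full((h, w), -1, dtype=np.int32)
    n_total = int(rng.poisson(p.target_density * p.area_mm2))

    cells: list[dict] = []          # geometry records, index = label
    cluster_ids: list[int] = []
    placed = 0
    next_cluster = 0
    margin = 2.0

    min_pixels = 6  # every placed cell must keep this many pixels of its own

    def try_place(cy, cx, a, b, theta, max_overlap, cluster=-2):
        """Claim unowned pixels for a new cell; return record or None.

        Isolated cells (``cluster == -2``) must not touch any existing
        cell, so each forms its own 8-connected component; cluster members
        may touch (and overlap up to ``max_overlap``) cells of their own
        cluster only.
        """
        ras = _raster_ellipse(cy, cx, a, b, theta, (h, w), dilate=1.6)
        if ras is None:
            return None
        yy, xx, r2, r2d = ras
        inside = r2 <= 1.0
        if not inside.any():
            return None
        # owners within the 1.6 px halo would 8-connect to the new cell
        near_owners = owner[yy[r2d <= 1.0], xx[r2d <= 1.0]]
        near_owners = np.unique(near_owners[near_owners >= 0])
        if cluster == -2:
            if near_owners.size:
                return None
        else:
            if any(cluster_ids[o] != cluster for o in near_owners):
                return None
        owned = owner[yy[inside], xx[inside]] >= 0
        if owned.mean() > max_overlap:
            return None
        free = inside.copy()
        free[inside] = ~owned
        if free.sum() < min_pixels:
            return None
        return {"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta,
                "yy": yy, "xx": xx, "r2": r2, "free": free}

    def commit(rec, cluster):
        nonlocal placed
        label = len(cells)
        yy, xx, free = rec["yy"], rec["xx"], rec["free"]
        owner[yy[free], xx[free]] = label
        amp = max(0.30, rng.normal(0.55, 0.08))
        prof = amp * np.exp(-rec["r2"] * 1.1)
        soft = rec["r2"] <= 1.4
        np.add.at(img, (yy[soft], xx[soft]), prof[soft])
        cells.append(rec)
        cluster_ids.append(cluster)
        placed += 1
        return label

    event_failures = 0
    while placed < n_total:
        size = 1
        if rng.random() < p.cluster_prob:
            size = 1 + int(rng.integers(1, 4))
        size = min(size, n_total - placed)
        is_cluster = size > 1
        cid = next_cluster if is_cluster else -1
        anchor = None
        for _ in range(80):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            a, b, theta = _sample_cell_geometry(rng, p)
            anchor = try_place(cy, cx, a, b, theta, max_overlap=0.6,
                               cluster=cid if is_cluster else -2)
            if anchor is not None:
                break
        if anchor is None:
            event_failures += 1
            if event_failures >= 10:  # field saturated; stop placing
                break
            continue
        event_failures = 0
        next_cluster += is_cluster
        commit(anchor, cid)
        prev = anchor
        for _ in range(size - 1):
            neighbor = None
            for _ in range(80):
                a2, b2, th2 = _sample_cell_geometry(rng, p)
                # center distance below the sum of semi-minor axes ->
                # components touch and merge under 8-connectivity
                d = rng.uniform(0.6, 0.95) * (prev["b"] + b2)
                ang = rng.uniform(0, 2 * np.pi)
                cy2 = np.clip(prev["cy"] + d * np.sin(ang), margin, h - margin)
                cx2 = np.clip(prev["cx"] + d * np.cos(ang), margin, w - margin)
                neighbor = try_place(cy2, cx2, a2, b2, th2, max_overlap=0.6,
                                     cluster=cid)
                if neighbor is not None:
                    break
            if neighbor is None:
                break
            commit(neighbor, cid)
            prev = neighbor

    # bright non-cell artifacts, excluded from the mask
    n_art = int(rng.poisson(p.artifact_rate * p.area_mm2))
    for _ in range(n_art):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        rad = rng.uniform(0.8, 2.0)
        amp = rng.uniform(0.4, 0.8)
        ras = _raster_ellipse(cy, cx, rad, rad, 0.0, (h, w))
        if ras is None:
            continue
        yy, xx, r2, _ = ras
        soft = r2 <= 2.0
        np.add.at(img, (yy[soft], xx[soft]), amp * np.exp(-r2[soft] * 2.0))

    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img16 = np.round(np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16)

    regions = _regions_from_owner(owner, cluster_ids, p.um_per_px)
    mask = owner >= 0
    density = len(regions) / p.area_mm2
    return Scene(
        image=ImageTile(img16, bit_depth=16, um_per_px=p.um_per_px),
        mask=mask,
        regions=regions,
        true_density=density,
        labels=owner,
        params=p,
    )


def _regions_from_owner(owner: np.ndarray, cluster_ids: list[int],
                        um_per_px: float) -> list[CellRegion]:
    regions = []
    n = len(cluster_ids)
    for label in range(n):
        ys, xs = np.nonzero(owner == label)
        if ys.size == 0:  # cannot happen by construction; guard anyway
            continue
        cy, cx = float(ys.mean()), float(xs.mean())
        ecc = moment_eccentricity(ys, xs)
        regions.append(
            CellRegion(
                label=label,
                centroid=(cy, cx),
                area_px=int(ys.size),
                area_um2=float(ys.size) * um_per_px**2,
                eccentricity=ecc,
                cluster_id=cluster_ids[label],
                pixels=np.column_stack([ys, xs]),
            )
        )
    return regions


def generate_mosaic(grid_rows: int, grid_cols: int, density_field,
                    params: SceneParams, spacing_mm: float | None = None) -> Mosaic:
    """Generate a grid of scenes with per-tile target densities.

    ``density_field`` maps ``(row, col)`` to a target density in cells/mm^2;
    every grid position must be present. ``spacing_mm`` is the physical tile
    pitch (e.g. 2.5 mm for an 8 x 8 grid covering a 20 x 20 mm^2 region);
    by default it equals the tile width so tiles abut.
    """
    if grid_rows <= 0 or grid_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if spacing_mm is None:
        spacing_mm = params.width_px * params.um_per_px / 1000.0
    tiles = {}
    for r in range(grid_rows):
        for c in range(grid_cols):
            if (r, c) not in density_field:
                raise ValueError(f"missing target density for grid cell {(r, c)}")
            child = int(
                np.random.SeedSequence((params.seed, r, c)).generate_state(1)[0]
                % 2**31
            )
            p = dataclasses.replace(
                params, target_density=float(density_field[(r, c)]), seed=child
            )
            tiles[(r, c)] = generate_scene(p)
    return Mosaic(grid_rows=grid_rows, grid_cols=grid_cols,
                  spacing_mm=float(spacing_mm), tiles=tiles)
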
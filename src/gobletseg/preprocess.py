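"""Contrast normalization and training-time augmentation.

The pipeline applies CLAHE to whole tiles, then draws random image/mask
crop pairs and expands them with right-angle rotations and flips. Masks are
transformed with nearest-neighbor semantics only (right-angle rotations and
flips are exact on the pixel grid), so binarity is preserved. Augmentation
is a training-time step only; the evaluation path never calls it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from .types import ImageTile, as_label_mask

__all__ = ["AugmentSpec", "apply_clahe", "random_crop_pair", "augment_pair"]


@dataclass
class AugmentSpec:
    """Augmentation plan: crops x rotations x flip variants.

    ``rotations`` holds angles from {0, 90, 180, 270} (degrees,
    counter-clockwise); ``flips`` is a subset of {"horizontal", "vertical"};
    the identity (no flip) is always included as a variant. Each source
    image therefore expands to ``n_crops_per_image * len(rotations) *
    (1 + len(flips))`` pairs.
    """

    crop_size_px: int = 512
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    flips: tuple[str, ...] = ("horizontal", "vertical")
    n_crops_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size_px <= 0:
            raise ValueError("crop_size_px must be positive")
        bad = set(self.rotations) - {0, 90, 180, 270}
        if bad:
            raise ValueError(f"rotations must be multiples of 90 deg, got {bad}")
        bad = set(self.flips) - {"horizontal", "vertical"}
        if bad:
            raise ValueError(f"unknown flips {bad}")
        if self.n_crops_per_image <= 0:
            raise ValueError("n_crops_per_image must be positive")

    @property
    def multiplicity(self) -> int:
        return self.n_crops_per_image * len(self.rotations) * (1 + len(self.flips))


def apply_clahe(tile: ImageTile, clip_limit: float = 0.01,
                grid: tuple[int, int] = (8, 8)) -> ImageTile:
    """Contrast-limited adaptive histogram equalization on a whole tile.

    ``clip_limit`` is the normalized clipping fraction; ``grid`` is the
    number of contextual tiles (rows, cols). Output keeps the input's shape,
    bit depth and calibration; the operation is deterministic.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    gr, gc = grid
    if gr < 1 or gc < 1:
        raise ValueError("grid dims must be >= 1")
    h, w = tile.shape
    if h < gr or w < gc:
        raise ValueError(f"tile {h}x{w} smaller than CLAHE grid {gr}x{gc}")
    top = 2**tile.bit_depth - 1
    if np.ptp(tile.pixels) == 0:
        # constant tile: nothing to equalize
        return ImageTile(tile.pixels.copy(), tile.bit_depth, tile.um_per_px)
    norm = tile.pixels.astype(np.float64) / top
    kernel = (max(1, h // gr), max(1, w // gc))
    eq = exposure.equalize_adapthist(norm, kernel_size=kernel,
                                     clip_limit=clip_limit)
    out = np.round(eq * top).astype(tile.pixels.dtype)
    return ImageTile(out, tile.bit_depth, tile.um_per_px)


def random_crop_pair(tile: ImageTile, mask: np.ndarray, spec: AugmentSpec,
                     rng: np.random.Generator | None = None):
    """One aligned square crop of an image/mask pair.

    The offset is uniform over all valid positions; image and mask use the
    identical offset.
    """
    mask = as_label_mask(mask)
    if mask.shape != tile.shape:
        raise ValueError("mask not co-registered with tile")
    s = spec.crop_size_px
    h, w = tile.shape
    if s > h or s > w:
        raise ValueError(f"crop {s} larger than image {h}x{w}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r0 = int(rng.integers(0, h - s + 1))
    c0 = int(rng.integers(0, w - s + 1))
    sub = ImageTile(tile.pixels[r0:r0 + s, c0:c0 + s].copy(),
                    tile.bit_depth, tile.um_per_px)
    return sub, mask[r0:r0 + s, c0:c0 + s].copy(), (r0, c0)


def _orient(arr: np.ndarray, rot: int, flip: str | None) -> np.ndarray:
    out = np.rot90(arr, k=rot // 90)
    if flip == "horizontal":
        out = out[:, ::-1]
    elif flip == "vertical":
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_pair(tile: ImageTile, mask: np.ndarray, spec: AugmentSpec):
    """Expand one image/mask pair into augmented training pairs.

    Returns a list of ``(ImageTile, mask, record)`` where ``record``
    documents (crop offset, rotation, flip) for the manifest. Rotation and
    flip are applied in lockstep to image and mask and preserve the
    foreground pixel count; cropping does not.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_crops_per_image):
        sub, submask, offset = random_crop_pair(tile, mask, spec, rng)
        for rot in spec.rotations:
            for flip in (None, *spec.flips):
                img = _orient(sub.pixels, rot, flip)
                msk = _orient(submask, rot, flip)
                out.append(
                    (
                        ImageTile(img, tile.bit_depth, tile.um_per_px),
                        msk,
                        {"offset": offset, "rotation": rot, "flip": flip or "none"},
                    )
                )
    return out
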
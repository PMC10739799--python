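"""File I/O: tiles as TIFF/PNG, masks as 0/255 PNG, probability maps as
32-bit TIFF, region tables and manifests as CSV, checkpoints as npz+YAML."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CellRegion, ImageTile

__all__ = ["read_tile", "write_tile", "read_mask", "write_mask",
           "read_prob", "write_prob", "regions_to_csv", "regions_from_csv",
           "save_checkpoint", "load_checkpoint", "provenance_header"]


def read_tile(path, um_per_px: float = 1.0) -> ImageTile:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:  # drop alpha/colour, keep luminance
        arr = arr[..., 0]
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return ImageTile(arr, bit_depth=bit_depth, um_per_px=um_per_px)


def write_tile(path, tile: ImageTile) -> None:
    path = Path(path)
    arr = tile.pixels
    if tile.bit_depth == 16 and arr.dtype != np.uint16:
        arr = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_prob(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_prob(path, prob: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(prob, dtype=np.float32))


def regions_to_csv(path, regions: list[CellRegion], tile: str = "") -> None:
    rows = [{
        "id": r.label, "tile": tile,
        "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
        "area_px": r.area_px, "area_um2": r.area_um2,
        "eccentricity": r.eccentricity, "cluster_id": r.cluster_id,
    } for r in regions]
    pd.DataFrame(rows, columns=["id", "tile", "centroid_row", "centroid_col",
                                "area_px", "area_um2", "eccentricity",
                                "cluster_id"]).to_csv(path, index=False)


def regions_from_csv(path) -> list[CellRegion]:
    df = pd.read_csv(path)
    return [CellRegion(label=int(r.id), centroid=(r.centroid_row, r.centroid_col),
                       area_px=int(r.area_px), area_um2=float(r.area_um2),
                       eccentricity=float(r.eccentricity),
                       cluster_id=int(getattr(r, "cluster_id", -1)))
            for r in df.itertuples()]


def save_checkpoint(path, model, arch: dict) -> None:
    """Weights as npz next to an architecture-describing YAML."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(arch, fh)


def load_checkpoint(path):
    """Returns (state_dict, arch_dict); the caller builds the model."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        state = {k: data[k] for k in data.files}
    with open(path.with_suffix(".yaml")) as fh:
        arch = yaml.safe_load(fh)
    return state, arch


def provenance_header(config: dict, seed: int, version: str) -> dict:
    """Provenance record attached to every pipeline artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": int(seed), "version": version}
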
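"""Reading and writing of images, ROIs, configs and study tables.

Angiograms are written as 16-bit grayscale TIFF; binary masks and
skeletons as 8-bit PNG (0/255); ROIs as JSON vertex lists; configuration
as YAML; tabular output as CSV.  Provenance-bearing text outputs start
with a comment line carrying the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import AngioImage, BinaryVesselMap, ROIPolygon, SkeletonMap

__all__ = [
    "read_image", "write_angiogram", "write_mask", "read_mask",
    "read_roi", "write_roi", "load_config", "dump_config",
    "write_table", "read_table", "config_hash",
]


def read_image(path: str | Path, modality: str = "AS-OCTA") -> AngioImage:
    """Load a grayscale TIFF/PNG (8- or 16-bit) and normalize to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    peak = arr.max()
    if peak > 1.0:
        scale = 65535.0 if peak > 255 else 255.0
        arr = arr / scale
    return AngioImage(arr, modality=modality, meta={"path": str(path)})


def write_angiogram(image: AngioImage, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF."""
    arr = np.clip(image.data, 0, 1)
    tifffile.imwrite(Path(path), (arr * 65535).round().astype(np.uint16))


def write_mask(mask: BinaryVesselMap | SkeletonMap | np.ndarray, path: str | Path) -> None:
    """Write a binary raster as 8-bit PNG with values {0, 255}."""
    arr = mask if isinstance(mask, np.ndarray) else mask.data
    iio.imwrite(Path(path), (np.asarray(arr) > 0).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def read_roi(path: str | Path) -> ROIPolygon:
    """ROI from a JSON file: ``{"vertices": [[x, y], ...]}`` or a bare list."""
    with open(path) as fh:
        data = json.load(fh)
    verts = data["vertices"] if isinstance(data, dict) else data
    return ROIPolygon(np.asarray(verts, dtype=float))


def write_roi(roi: ROIPolygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"vertices": roi.vertices.tolist()}, fh, indent=1)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (order-insensitive)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *, config_hash: str = "",
                seed: int | None = None, float_format: str = "%.6f") -> None:
    """CSV with a provenance comment header; byte-stable for fixed input."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# cvquant config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format=float_format, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
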
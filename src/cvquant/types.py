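"""Core data containers shared across the pipeline.

All rasters use 0-based, row-major indexing with the origin at the top-left
pixel.  Intensity images are floats normalized to [0, 1]; binary rasters are
``uint8`` with values in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "AngioImage",
    "EnhancedImage",
    "ROIPolygon",
    "BinaryVesselMap",
    "SkeletonMap",
    "VesselMetrics",
    "StudyRecord",
]

MIN_IMAGE_DIM = 16


@dataclass
class AngioImage:
    """A 2-D grayscale en-face angiogram with acquisition metadata.

    Parameters
    ----------
    data:
        2-D float array of intensities in [0, 1].
    pixel_size_um:
        Physical pixel pitch in micrometres, if known.
    modality:
        ``"AS-OCTA"`` or ``"ICGA"`` (free-form tags are tolerated).
    meta:
        Free-form metadata (eye ID, visit week, treatment arm, ...).
    """

    data: np.ndarray
    pixel_size_um: float | None = None
    modality: str = "AS-OCTA"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.data.ndim}")
        if min(self.data.shape) < MIN_IMAGE_DIM:
            raise ValueError(
                f"image dimensions {self.data.shape} below minimum "
                f"{MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class EnhancedImage:
    """A non-negative filter-response raster with its filter provenance.

    ``provenance`` is an ordered list of ``(filter_name, params)`` pairs
    recording every operation applied since the source image.
    """

    data: np.ndarray
    provenance: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("enhanced response must be 2-D")
        if np.any(self.data < 0):
            raise ValueError("enhanced response must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ROIPolygon:
    """A simple polygon delimiting the analysis region.

    Vertices are ``(x, y)`` pairs in 0-based pixel coordinates; containment
    is decided at pixel centers by the even-odd (crossing-number) rule.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) pairs")
        if len(self.vertices) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")

    def validate_simple(self) -> None:
        from shapely.geometry import Polygon

        poly = Polygon(self.vertices)
        if not poly.is_simple:
            raise ValueError("ROI polygon is self-intersecting")
        if poly.area == 0:
            raise ValueError("ROI polygon has zero area")

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "ROIPolygon":
        """Rectangle covering every pixel center of a ``(rows, cols)`` frame."""
        h, w = shape
        return cls(np.array([
            (-0.5, -0.5), (w - 0.5, -0.5), (w - 0.5, h - 0.5), (-0.5, h - 0.5),
        ]))


@dataclass
class BinaryVesselMap:
    """Vessel/background partition: vessel pixels 1, background 0."""

    data: np.ndarray
    roi: ROIPolygon | None = None
    provenance: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("binary map must be 2-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("binary map values must be in {0, 1}")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SkeletonMap:
    """One-pixel-wide centerline raster derived from a vessel map."""

    data: np.ndarray
    parent: BinaryVesselMap | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("skeleton must be 2-D")
        self.data = (arr > 0).astype(np.uint8)


@dataclass
class VesselMetrics:
    """The three scalar vessel descriptors for one image/ROI.

    vd:
        Vessel density, vessel-pixel count as % of ROI pixel count.
    vba:
        Vessel branch area, centerline-pixel count as % of ROI pixel count.
    vw:
        Vessel width, ``vd / vba`` — mean vessel calibre in pixels.  ``nan``
        with ``vw_defined=False`` when the map is empty (``vba == 0``).
    """

    vd: float
    vba: float
    vw: float
    roi_px: int
    vw_defined: bool = True
    eye: str | None = None
    week: float | None = None
    arm: str | None = None


@dataclass
class StudyRecord:
    """One eye-visit row joining imaging metrics and clinical covariates.

    ``stage`` is the visually graded ICGA vascularisation stage (1-5);
    ``leakage_s`` the dye leakage time in seconds; ``cytokines`` maps analyte
    name to concentration (``nan`` when below the limit of detection) and
    ``below_lod`` flags which analytes were censored.
    """

    eye: str
    week: float
    arm: str
    metrics: VesselMetrics | None = None
    true_vd: float | None = None
    stage: int | None = None
    leakage_s: float | None = None
    cytokines: dict[str, float] = field(default_factory=dict)
    below_lod: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage is not None and self.stage not in (1, 2, 3, 4, 5):
            raise ValueError(f"ICGA stage must be in 1..5, got {self.stage}")
        if self.leakage_s is not None and self.leakage_s <= 0:
            raise ValueError("leakage time must be positive")
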
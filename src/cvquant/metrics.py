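"""Skeleton-based vessel morphometry: VD, VBA and VW.

Definitions, all relative to the analysed region (ROI):

- vessel density        VD (%)  = vessel pixels / ROI pixels x 100
- vessel branch area    VBA (%) = centerline pixels / ROI pixels x 100
- vessel width          VW      = VD / VBA

VBA's numerator is the pixel count of the one-pixel-wide skeleton, so VW
equals the mean vessel calibre in pixels; this is why VD and VBA share the
same normalizer.  Skeleton "length" is by default the plain pixel count; a
Euclidean variant weighting diagonal steps by sqrt(2) is available.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis, skeletonize as _sk_skeletonize, thin as _sk_thin

from .segment import rasterize_roi
from .types import BinaryVesselMap, SkeletonMap, VesselMetrics

__all__ = [
    "vessel_density",
    "skeletonize",
    "vessel_branch_area",
    "vessel_width",
    "compute_metrics",
    "skeleton_length",
]


def _roi_mask(vmap: BinaryVesselMap) -> np.ndarray:
    if vmap.roi is None:
        raise ValueError("vessel map has no ROI attached; crop it first")
    mask = rasterize_roi(vmap.roi, vmap.shape)
    if not mask.any():
        raise ValueError("ROI contains no pixels")
    return mask


def vessel_density(vmap: BinaryVesselMap) -> float:
    """Vessel pixels inside the ROI as a percentage of ROI pixels."""
    roi = _roi_mask(vmap)
    return 100.0 * int((vmap.data.astype(bool) & roi).sum()) / int(roi.sum())


def skeletonize(vmap: BinaryVesselMap, method: str = "zhang") -> SkeletonMap:
    """Topology-preserving thinning to one-pixel-wide centerlines.

    ``method="zhang"`` uses Zhang-Suen-style iterative thinning;
    ``method="medial"`` the medial-axis transform.  The number of connected
    components is preserved.
    """
    binary = vmap.data.astype(bool)
    if method == "zhang":
        skel = _sk_skeletonize(binary, method="zhang")
        # Zhang-Suen can leave 2x2 staircase blocks; one topology-preserving
        # thinning pass removes the redundant pixels
        skel = _sk_thin(skel)
    elif method == "medial":
        skel = medial_axis(binary)
    else:
        raise ValueError(f"unknown thinning method {method!r}")
    return SkeletonMap(skel.astype(np.uint8), parent=vmap)


def skeleton_length(skeleton: SkeletonMap, weighting: str = "pixel") -> float:
    """Total centerline length in px.

    ``"pixel"`` counts skeleton pixels; ``"euclidean"`` sums 8-neighbour
    step lengths (1 for axial, sqrt(2) for diagonal) over the skeleton
    graph, counting each edge once.
    """
    sk = skeleton.data.astype(bool)
    if weighting == "pixel":
        return float(sk.sum())
    if weighting != "euclidean":
        raise ValueError(f"unknown weighting {weighting!r}")
    length = 0.0
    # axial neighbours
    length += float((sk[:, :-1] & sk[:, 1:]).sum())
    length += float((sk[:-1, :] & sk[1:, :]).sum())
    # diagonal neighbours
    length += np.sqrt(2.0) * float((sk[:-1, :-1] & sk[1:, 1:]).sum())
    length += np.sqrt(2.0) * float((sk[:-1, 1:] & sk[1:, :-1]).sum())
    # isolated pixels contribute one unit each
    lbl, n = ndimage.label(sk, structure=np.ones((3, 3), int))
    sizes = ndimage.sum_labels(sk, lbl, index=np.arange(1, n + 1))
    length += float((sizes == 1).sum())
    return length


def vessel_branch_area(skeleton: SkeletonMap, vmap: BinaryVesselMap) -> float:
    """Centerline pixels inside the ROI as a percentage of ROI pixels."""
    roi = _roi_mask(vmap)
    return 100.0 * int((skeleton.data.astype(bool) & roi).sum()) / int(roi.sum())


def vessel_width(vd: float, vba: float) -> tuple[float, bool]:
    """VW = VD / VBA; ``(nan, False)`` for an empty map (VBA = 0)."""
    if vba < 0:
        raise ValueError("VBA must be >= 0")
    if vba == 0:
        return float("nan"), False
    return vd / vba, True


def compute_metrics(vmap: BinaryVesselMap, method: str = "zhang",
                    eye: str | None = None, week: float | None = None,
                    arm: str | None = None) -> VesselMetrics:
    """VD, VBA and VW for one cropped vessel map."""
    roi = _roi_mask(vmap)
    vd = vessel_density(vmap)
    skel = skeletonize(vmap, method=method)
    vba = vessel_branch_area(skel, vmap)
    vw, defined = vessel_width(vd, vba)
    return VesselMetrics(vd=vd, vba=vba, vw=vw, roi_px=int(roi.sum()),
                         vw_defined=defined, eye=eye, week=week, arm=arm)
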
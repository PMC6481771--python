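"""Distance-dependent acuity blurring and acuity-disk grid sampling.

A viewer with spatial acuity ``a`` cycles per degree cannot resolve detail
finer than its minimum resolvable angle MRA = 1/(2a) degrees.  At viewing
distance d the MRA projects to an object-plane length

    MRA_mm = 1000 * d_m * tan(MRA in radians)

Catch images are low-pass filtered with an isotropic Gaussian of

    sigma_px = k * MRA_mm * px_per_mm

where k (default 0.5) is a fixed shape constant relating the resolution
limit to the Gaussian width; it is configurable so users can match other
acuity-filter conventions.  Reflective edge padding preserves patch means
near the image border.  For statistics, images are sampled on a square grid
spaced one acuity disk (the kernel FWHM, rounded up to whole pixels) apart,
so that neighboring samples are approximately independent observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .viewers import ViewerModel

__all__ = [
    "ViewingGeometry",
    "DEFAULT_DISTANCES_M",
    "mra_object_plane_mm",
    "acuity_sigma_px",
    "acuity_disk_px",
    "blur_for_acuity",
    "acuity_grid_sample",
]

#: Modeled viewing distances, metres: a near-field display distance plus the
#: 2/4/8/16 m far-field series.
DEFAULT_DISTANCES_M = (1.0, 2.0, 4.0, 8.0, 16.0)

#: Gaussian width as a fraction of the object-plane MRA.
DEFAULT_KERNEL_SHAPE_K = 0.5

#: FWHM of a unit-sigma Gaussian.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewing distance (m) and object-plane spatial calibration (px/mm)."""

    distance_m: float
    px_per_mm: float

    def __post_init__(self) -> None:
        if self.distance_m <= 0 or self.px_per_mm <= 0:
            raise ValueError("distance and px_per_mm must be positive")


def mra_object_plane_mm(acuity_cpd: float, distance_m: float) -> float:
    """Minimum resolvable angle projected to the object plane, mm."""
    if acuity_cpd <= 0 or distance_m <= 0:
        raise ValueError("acuity and distance must be positive")
    mra_deg = 1.0 / (2.0 * acuity_cpd)
    return 1000.0 * distance_m * np.tan(np.deg2rad(mra_deg))


def acuity_sigma_px(
    viewer: ViewerModel, geom: ViewingGeometry, k: float = DEFAULT_KERNEL_SHAPE_K
) -> float:
    """Gaussian blur width in pixels for this viewer and geometry."""
    return k * mra_object_plane_mm(viewer.acuity_cpd, geom.distance_m) * geom.px_per_mm


def acuity_disk_px(
    viewer: ViewerModel, geom: ViewingGeometry, k: float = DEFAULT_KERNEL_SHAPE_K
) -> int:
    """Acuity-disk diameter = blur kernel FWHM, rounded up to whole pixels."""
    d = _FWHM_PER_SIGMA * acuity_sigma_px(viewer, geom, k)
    return max(1, int(np.ceil(d)))


def blur_for_acuity(
    image: np.ndarray,
    viewer: ViewerModel,
    geom: ViewingGeometry,
    k: float = DEFAULT_KERNEL_SHAPE_K,
) -> np.ndarray:
    """Low-pass an image to what the viewer can resolve at this distance.

    Gaussian blur with reflective padding; a constant image and the image
    mean are preserved, and sigma scales linearly with distance.
    """
    sigma = acuity_sigma_px(viewer, geom, k)
    img = np.asarray(image, dtype=float)
    if sigma < 1e-3:
        return img.copy()
    return gaussian_filter(img, sigma=sigma, mode="reflect")


def acuity_grid_sample(
    image: np.ndarray,
    roi_mask: np.ndarray | None,
    disk_px: float,
    fallback_center: bool = False,
) -> np.ndarray:
    """Sample pixel values on a square grid spaced one acuity disk apart.

    Grid nodes falling outside the ROI mask are dropped.  When the grid
    leaves no node inside the ROI (disk larger than the patch), raises a
    sampling error, or with ``fallback_center`` returns the single pixel
    nearest the ROI centroid — the one look a viewer of that acuity gets.
    """
    if disk_px < 1:
        raise ValueError("disk_px must be >= 1")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    step = int(round(disk_px))
    off = step // 2
    rows = np.arange(off, h, step)
    cols = np.arange(off, w, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if roi_mask is not None:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("ROI mask must match the image shape")
        keep = mask[rr, cc]
    else:
        keep = np.ones(rr.shape, dtype=bool)
    vals = img[rr[keep], cc[keep]]
    if vals.size == 0:
        if fallback_center and roi_mask is not None and mask.any():
            ry, cx = np.nonzero(mask)
            cy, cxm = ry.mean(), cx.mean()
            k = np.argmin((ry - cy) ** 2 + (cx - cxm) ** 2)
            return np.array([img[ry[k], cx[k]]])
        raise ValueError("acuity grid leaves no samples inside the ROI")
    return vals
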
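"""Geometric accuracy, intensity uniformity and ghosting from a disk phantom.

The three classic ACR/NEMA tests on the single-disk phantom:

* geometric accuracy — detect the disk as an ellipse and report the
  maximum percentage radius error against the designed radius,
* percent intensity uniformity (PIU) — extrema of a 3x3 low-pass-filtered
  image inside the eroded disk: ``100 * (1 - (Imax-Imin)/(Imax+Imin))``,
* ghosting ratio — asymmetry between phase-encode-axis (top/bottom) and
  frequency-encode-axis (left/right) background rectangles, normalized by
  the disk mean: ``|(top+bottom) - (left+right)| / (2 * disk)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, correlate
from skimage.measure import label, regionprops
from skimage.morphology import disk as disk_footprint

from .phantoms import PhantomImage

__all__ = [
    "DetectedEllipse",
    "GhostingROIs",
    "detect_disk",
    "eroded_disk_roi",
    "geometric_accuracy",
    "intensity_uniformity",
    "ghosting_ratio",
    "build_ghosting_rois",
    "DiskDetectionError",
]

EROSION_RADIUS_PX = 5

# NEMA nine-point low-pass kernel (binomial weights).
NEMA_KERNEL = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0


class DiskDetectionError(RuntimeError):
    """Raised when no disk can be grown from the image-center seed."""


@dataclass(frozen=True)
class DetectedEllipse:
    """Equivalent ellipse of the region-grown disk, semi-axes in mm."""

    center_px: tuple[float, float]  # (row, col), sub-pixel
    r_major_mm: float
    r_minor_mm: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.r_major_mm >= self.r_minor_mm > 0):
            raise ValueError("require r_major >= r_minor > 0")


@dataclass(frozen=True)
class GhostingROIs:
    """Four background rectangles plus the eroded in-disk ROI.

    Each rectangle is stored as (row_slice, col_slice); the long edge is
    N/2, the short edge N/16, centered 7N/16 pixels from the disk center.
    """

    top: tuple[slice, slice]
    bottom: tuple[slice, slice]
    left: tuple[slice, slice]
    right: tuple[slice, slice]
    disk_roi: np.ndarray


def detect_disk(image: PhantomImage) -> DetectedEllipse:
    """Region-grow the central disk and fit its equivalent ellipse.

    The region is the 4-connected component, seeded at the image center,
    of pixels above half the robust foreground level (median of a small
    central patch).  Semi-axes come from the second central moments of
    the binary region (sub-pixel, deterministic) converted to mm.
    """
    mag = image.magnitude
    n = mag.shape[0]
    c = n // 2
    fg = float(np.median(mag[c - 2 : c + 3, c - 2 : c + 3]))
    threshold = 0.5 * fg
    if threshold <= 0 or mag[c, c] < threshold:
        raise DiskDetectionError("no disk found at the image-center seed")
    labels = label(mag >= threshold, connectivity=1)
    mask = labels == labels[c, c]
    props = regionprops(mask.astype(np.uint8))[0]
    r_major = 0.5 * props.axis_major_length * image.pixel_mm
    r_minor = 0.5 * props.axis_minor_length * image.pixel_mm
    return DetectedEllipse(
        center_px=tuple(props.centroid),
        r_major_mm=float(r_major),
        r_minor_mm=float(r_minor),
        mask=mask,
    )


def geometric_accuracy(ellipse: DetectedEllipse, r_ground_truth_mm: float) -> float:
    """Maximum percentage radius error of the detected ellipse, in percent."""
    if r_ground_truth_mm <= 0:
        raise ValueError("ground-truth radius must be positive")
    gt = r_ground_truth_mm
    return 100.0 * max(
        abs(ellipse.r_major_mm - gt) / gt,
        abs(ellipse.r_minor_mm - gt) / gt,
    )


def eroded_disk_roi(ellipse: DetectedEllipse, radius_px: int = EROSION_RADIUS_PX) -> np.ndarray:
    """Disk mask eroded by an isotropic disk-shaped structuring element."""
    roi = binary_erosion(ellipse.mask, structure=disk_footprint(radius_px))
    if not roi.any():
        raise ValueError("eroded disk ROI is empty")
    return roi


def intensity_uniformity(image: PhantomImage, ellipse: DetectedEllipse) -> float:
    """Percent intensity uniformity within the eroded disk, in [0, 100].

    The image is low-pass filtered with the NEMA nine-point binomial
    kernel (reflect boundary) before taking the in-ROI extrema.
    """
    roi = eroded_disk_roi(ellipse)
    filtered = correlate(image.magnitude, NEMA_KERNEL, mode="reflect")
    imax = float(filtered[roi].max())
    imin = float(filtered[roi].min())
    return 100.0 * (1.0 - (imax - imin) / (imax + imin))


def build_ghosting_rois(image: PhantomImage, ellipse: DetectedEllipse) -> GhostingROIs:
    """Place the four N/2 x N/16 background rectangles around the designed center.

    ROIs live in the phantom's frame (image center), decoupled from the
    detected centroid; the short edge spans N/16 pixels centered 7N/16
    from the center, the long edge N/2 pixels.
    """
    n = image.magnitude.shape[0]
    if n % 16:
        raise ValueError("ghosting ROI geometry requires N divisible by 16")
    c = n // 2
    off = 7 * n // 16
    half_long = n // 4
    half_short = n // 32
    long_sl = slice(c - half_long, c + half_long)

    def short(center: int) -> slice:
        sl = slice(center - half_short, center + half_short)
        if sl.start < 0 or sl.stop > n:
            raise ValueError("ghosting ROI outside image bounds")
        return sl

    return GhostingROIs(
        top=(short(c - off), long_sl),
        bottom=(short(c + off), long_sl),
        left=(long_sl, short(c - off)),
        right=(long_sl, short(c + off)),
        disk_roi=eroded_disk_roi(ellipse),
    )


def ghosting_ratio(image: PhantomImage, rois: GhostingROIs) -> float:
    """Normalized top/bottom vs left/right background asymmetry (unitless)."""
    mag = image.magnitude
    means = {k: float(mag[getattr(rois, k)].mean()) for k in ("top", "bottom", "left", "right")}
    disk_mean = float(mag[rois.disk_roi].mean())
    if disk_mean <= 0:
        raise ValueError("mean disk intensity must be positive")
    num = abs((means["top"] + means["bottom"]) - (means["left"] + means["right"]))
    return num / (2.0 * disk_mean)
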
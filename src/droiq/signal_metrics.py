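"""Edge sharpness (Lorentzian FWHM of the ESF derivative) and difference SNR.

Sharpness exploits the circular symmetry of the disk phantom: the
distance of every pixel center to the *designed* disk center provides a
naturally oversampled radial edge profile (edge spread function, ESF)
without any interpolation across the edge.  The scattered profile is
averaged onto a uniform grid at 1/10-pixel spacing; for noisy images the
profile is replaced by a 4-parameter logistic (sigmoid) fit for noise
robustness.  The (negated) derivative of the profile is then fitted with
a 4-parameter Lorentzian

    L(x | x0, G, A, B) = A * (1/pi) * (G/2) / ((x - x0)^2 + (G/2)^2) + B

whose full width at half maximum ``G`` (mm) is the sharpness metric.

SNR follows the NEMA two-acquisition difference method: two images of
the same object differing only in noise realization are subtracted, and
``SNR = sqrt(2) * mean(I1 in disk ROI) / std(I1 - I2 in disk ROI)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import DetectedEllipse, eroded_disk_roi
from .phantoms import PhantomImage

__all__ = [
    "EdgeSpreadFunction",
    "LorentzianFit",
    "FitFailure",
    "lorentzian",
    "logistic",
    "extract_esf",
    "fit_lorentzian",
    "snr_difference",
]


class FitFailure(RuntimeError):
    """Curve fit did not converge; carries the initialization used."""

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = p0


@dataclass(frozen=True)
class EdgeSpreadFunction:
    """Radial edge profile on a uniform distance grid (1/10-pixel spacing)."""

    distance_mm: np.ndarray
    intensity: np.ndarray
    window_mm: tuple[float, float]
    pixel_mm: float


@dataclass(frozen=True)
class LorentzianFit:
    amplitude: float
    offset: float
    fwhm_mm: float
    center_mm: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fitted FWHM must be positive")


def lorentzian(x: np.ndarray, x0: float, gamma: float, a: float, b: float) -> np.ndarray:
    """Area-normalized Lorentzian of FWHM ``gamma`` scaled by ``a``, offset ``b``."""
    half = gamma / 2.0
    return a * (1.0 / np.pi) * half / ((x - x0) ** 2 + half**2) + b


def logistic(x: np.ndarray, lo: float, hi: float, x0: float, s: float) -> np.ndarray:
    """Decreasing 4-parameter logistic: ``hi`` inside the disk, ``lo`` outside."""
    return lo + (hi - lo) / (1.0 + np.exp(np.clip((x - x0) / s, -500, 500)))


def extract_esf(
    image: PhantomImage,
    center_mm: tuple[float, float] = (0.0, 0.0),
    radius_mm: float = 95.0,
    window_halfwidth_px: float = 8.0,
    fit_sigmoid: bool | None = None,
) -> EdgeSpreadFunction:
    """Radial ESF of the disk edge against distance to the designed center.

    Pixels within ``radius_mm +/- window_halfwidth_px`` pixels of the
    center are bin-averaged onto a grid with 1/10-pixel spacing.  When
    ``fit_sigmoid`` is true (default: the generating spec is noisy) the
    binned profile is replaced by its logistic fit.
    """
    mag = image.magnitude
    delta = image.pixel_mm
    ax = image.grid.pixel_axis()
    xx, yy = np.meshgrid(ax, ax)
    dist = np.hypot(xx - center_mm[0], yy - center_mm[1])
    half = window_halfwidth_px * delta
    lo, hi = radius_mm - half, radius_mm + half
    if lo <= 0 or hi > np.hypot(ax[-1], ax[-1]):
        raise ValueError("ESF window falls outside the image")
    sel = (dist >= lo) & (dist <= hi)
    if not sel.any():
        raise ValueError("ESF window contains no pixels")

    step = delta / 10.0
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    idx = np.clip(np.rint((dist[sel] - lo) / step).astype(int), 0, len(grid) - 1)
    sums = np.bincount(idx, weights=mag[sel], minlength=len(grid))
    counts = np.bincount(idx, minlength=len(grid))
    filled = counts > 0
    esf = np.empty_like(grid)
    esf[filled] = sums[filled] / counts[filled]
    if not filled.all():  # interpolate across empty bins
        esf[~filled] = np.interp(grid[~filled], grid[filled], esf[filled])

    if fit_sigmoid is None:
        fit_sigmoid = bool(image.spec is not None and image.spec.noise_sigma > 0)
    if fit_sigmoid:
        n_tail = max(len(grid) // 8, 2)
        p0 = (float(esf[-n_tail:].mean()), float(esf[:n_tail].mean()), radius_mm, delta / 2.0)
        try:
            popt, _ = curve_fit(logistic, grid, esf, p0=p0, maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - pathological inputs
            raise FitFailure(f"sigmoid fit failed: {exc}", p0=p0) from exc
        esf = logistic(grid, *popt)

    return EdgeSpreadFunction(
        distance_mm=grid, intensity=esf, window_mm=(lo, hi), pixel_mm=delta
    )


def fit_lorentzian(esf: EdgeSpreadFunction) -> LorentzianFit:
    """Fit the negated ESF derivative with a 4-parameter Lorentzian.

    The ESF decreases outward, so the central-difference derivative is
    negated to a positive peak.  Initialization: amplitude from the peak
    area, center at the extremum, width from the half-maximum crossings.
    """
    x = esf.distance_mm
    y = esf.intensity
    deriv = -np.gradient(y, x)
    peak_i = int(np.argmax(deriv))
    if peak_i < 10 or peak_i > len(x) - 11:
        raise FitFailure("edge extremum too close to the window boundary")
    peak = float(deriv[peak_i])
    if peak <= 0:
        raise FitFailure("ESF has no decreasing edge in the window")
    half = peak / 2.0
    left = np.where(deriv[:peak_i] < half)[0]
    right = np.where(deriv[peak_i:] < half)[0]
    gamma0 = (
        x[peak_i + right[0]] - x[left[-1]]
        if len(left) and len(right)
        else 2.0 * esf.pixel_mm
    )
    p0 = (float(x[peak_i]), float(max(gamma0, 1e-3)), float(np.trapezoid(deriv, x)), 0.0)
    try:
        popt, _ = curve_fit(
            lorentzian,
            x,
            deriv,
            p0=p0,
            bounds=([x[0], 1e-6, -np.inf, -np.inf], [x[-1], np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailure(f"Lorentzian fit failed: {exc}", p0=p0) from exc
    resid = lorentzian(x, *popt) - deriv
    denom = float(np.linalg.norm(deriv)) or 1.0
    return LorentzianFit(
        amplitude=float(popt[2]),
        offset=float(popt[3]),
        fwhm_mm=float(popt[1]),
        center_mm=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid)) / denom,
    )


def snr_difference(
    image1: PhantomImage, image2: PhantomImage, ellipse: DetectedEllipse
) -> float:
    """NEMA difference-image SNR over the eroded disk ROI.

    Symmetric in its inputs up to which image supplies the signal mean;
    the sqrt(2) accounts for the doubled noise variance of a difference.
    """
    roi = eroded_disk_roi(ellipse)
    diff = image1.magnitude[roi] - image2.magnitude[roi]
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        raise ValueError("difference image has zero variance (identical inputs?)")
    return float(np.sqrt(2.0) * image1.magnitude[roi].mean() / sd)
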
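"""Analytic k-space phantoms and the reference inverse-FFT reconstruction.

The test objects are unions of uniform disks defined in *continuous* 2-D
k-space.  A disk of radius ``R`` (mm), intensity ``I`` and center
``(xc, yc)`` has the exact Fourier transform

    F(kx, ky) = Jinc(kr | R) * I * exp(-2*pi*i*(xc*kx + yc*ky)),
    Jinc(kr | R) = 2*pi*R**2 * J1(2*pi*R*kr) / (2*pi*R*kr),

with ``kr = sqrt(kx**2 + ky**2)`` and ``J1`` the first-order Bessel
function of the first kind.  Compound phantoms are sums of disk spectra.
The continuous spectrum is sampled on a DC-centered N x N grid with
spacing ``1/FOV``, optionally corrupted with complex Gaussian noise, and
reconstructed by a scaled inverse DFT so that the noiseless interior of a
disk reconstructs to its designed intensity ``I``.  This mimics an MR
acquisition of a continuous object onto a discrete image, so the digital
object carries no rasterization error of its own.

Amplitude convention
--------------------
The image is the Riemann sum of the inverse Fourier integral:
``img = ifft2(samples) * N**2 / FOV**2`` (DC-centered shifts applied on
both sides).  Noise with per-channel image-domain standard deviation
``sigma`` therefore corresponds to per-channel k-space standard deviation
``sigma * FOV**2 / N``.  ``sigma`` is quoted in the image domain so that
the designed SNR of a disk is simply ``I / sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import j1

__all__ = [
    "DiskSpec",
    "KSpaceGrid",
    "KSpaceData",
    "PhantomImage",
    "PhantomSpec",
    "jinc",
    "disk_kspace",
    "compound_kspace",
    "add_complex_noise",
    "ifft_reconstruct",
    "build_disk_phantom",
    "build_resolution_phantom",
    "build_lowcontrast_phantom",
    "realize",
    "realize_kspace",
    "realization_rng",
]


class LayoutError(ValueError):
    """Raised when a compound-phantom layout violates containment/overlap rules."""


@dataclass(frozen=True)
class DiskSpec:
    """One analytic disk: radius and center in mm, dimensionless intensity."""

    radius_mm: float
    intensity: float
    xc_mm: float = 0.0
    yc_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"disk radius must be positive, got {self.radius_mm}")


@dataclass(frozen=True)
class KSpaceGrid:
    """DC-centered square sampling grid with spacing 1/FOV in both axes.

    Sample ``n`` (0-based) sits at spatial frequency ``(n - N/2) / FOV``;
    the DC sample is at index ``N // 2``.  Image pixels are centered at
    ``(m - N/2) * FOV / N`` so the FOV center falls on pixel ``N // 2``.
    """

    fov_mm: float
    matrix_size: int

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.matrix_size < 2 or self.matrix_size % 2:
            raise ValueError("matrix_size must be an even integer >= 2")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    @property
    def delta_k(self) -> float:
        return 1.0 / self.fov_mm

    def freq_axis(self) -> np.ndarray:
        """1-D spatial-frequency coordinates (cycles/mm), DC at index N//2."""
        n = self.matrix_size
        return (np.arange(n) - n // 2) / self.fov_mm

    def kx(self) -> np.ndarray:
        """Horizontal frequency coordinate, varying along columns."""
        f = self.freq_axis()
        return np.broadcast_to(f[None, :], (self.matrix_size, self.matrix_size))

    def ky(self) -> np.ndarray:
        """Vertical frequency coordinate, varying along rows."""
        f = self.freq_axis()
        return np.broadcast_to(f[:, None], (self.matrix_size, self.matrix_size))

    def kr(self) -> np.ndarray:
        return np.hypot(self.kx(), self.ky())

    def pixel_axis(self) -> np.ndarray:
        """1-D image coordinates of pixel centers (mm), origin at FOV center."""
        n = self.matrix_size
        return (np.arange(n) - n // 2) * self.pixel_mm


@dataclass(frozen=True)
class KSpaceData:
    """Complex samples of a phantom spectrum aligned to a :class:`KSpaceGrid`."""

    values: np.ndarray
    grid: KSpaceGrid
    is_noisy: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        n = self.grid.matrix_size
        if v.ndim != 2 or v.shape != (n, n):
            raise ValueError(f"k-space values must be {n}x{n}, got {v.shape}")


@dataclass(frozen=True)
class PhantomImage:
    """Reconstructed complex image plus its magnitude and provenance."""

    complex_image: np.ndarray
    grid: KSpaceGrid
    spec: "PhantomSpec | None" = None
    magnitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitude", np.abs(self.complex_image))

    @property
    def pixel_mm(self) -> float:
        return self.grid.pixel_mm


@dataclass(frozen=True)
class PhantomSpec:
    """A named phantom: disk list, grid, noise level and layout metadata.

    ``kind`` is one of ``disk``, ``resolution``, ``low_contrast``.  The
    ``layout`` dict records kind-specific geometry (block/spoke positions)
    needed by the downstream metrics; it is JSON-serializable.
    """

    kind: str
    disks: tuple[DiskSpec, ...]
    grid: KSpaceGrid
    noise_sigma: float
    seed: int = 0
    layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "resolution", "low_contrast"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.disks:
            raise ValueError("phantom must contain at least one disk")
        if self.kind == "disk" and len(self.disks) != 1:
            raise ValueError("a simple disk phantom has exactly one disk")


def jinc(kr: np.ndarray | float, radius_mm: float) -> np.ndarray | float:
    """Radial spectrum of a unit-intensity disk: 2*pi*R^2 * J1(2*pi*R*kr)/(2*pi*R*kr).

    Takes the analytic limit pi*R^2 at ``kr = 0``.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    kr_arr = np.asarray(kr, dtype=float)
    z = 2.0 * np.pi * radius_mm * kr_arr
    safe = np.where(z == 0.0, 1.0, z)
    ratio = np.where(z == 0.0, 0.5, j1(safe) / safe)
    out = 2.0 * np.pi * radius_mm**2 * ratio
    return float(out) if np.isscalar(kr) else out


def disk_kspace(grid: KSpaceGrid, disk: DiskSpec) -> KSpaceData:
    """Sample the continuous spectrum of one disk on the grid.

    Off-centering appears as the linear phase ramp
    ``exp(-2*pi*i*(xc*kx + yc*ky))`` (Fourier shift theorem); a centered
    disk has an exactly real spectrum.
    """
    values = jinc(grid.kr(), disk.radius_mm) * disk.intensity
    if disk.xc_mm != 0.0 or disk.yc_mm != 0.0:
        phase = np.exp(-2j * np.pi * (disk.xc_mm * grid.kx() + disk.yc_mm * grid.ky()))
        values = values * phase
    return KSpaceData(values=np.asarray(values, dtype=complex), grid=grid)


def compound_kspace(grid: KSpaceGrid, disks: Sequence[DiskSpec]) -> KSpaceData:
    """Sum of per-disk spectra (linearity of the Fourier transform)."""
    if len(disks) == 0:
        raise ValueError("compound phantom needs at least one disk")
    total = np.zeros((grid.matrix_size, grid.matrix_size), dtype=complex)
    for d in disks:
        total += disk_kspace(grid, d).values
    return KSpaceData(values=total, grid=grid)


def _kspace_noise_sigma(grid: KSpaceGrid, sigma: float) -> float:
    # per-channel k-space std that yields per-channel image std == sigma
    return sigma * grid.fov_mm**2 / grid.matrix_size


def add_complex_noise(
    kspace: KSpaceData,
    sigma: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> KSpaceData:
    """Add zero-mean complex Gaussian acquisition noise to k-space samples.

    ``sigma`` is the image-domain per-channel (real and imaginary) noise
    standard deviation after :func:`ifft_reconstruct`, so a disk of
    intensity ``I`` has designed SNR ``I / sigma``.  The noise is i.i.d.
    per sample and not Hermitian-symmetrized, so magnitude images have a
    Rician/Rayleigh background.  Same seed and input give the same output.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return kspace
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = kspace.grid.matrix_size
    scale = _kspace_noise_sigma(kspace.grid, sigma)
    noise = rng.normal(0.0, scale, (n, n)) + 1j * rng.normal(0.0, scale, (n, n))
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return KSpaceData(
        values=kspace.values + noise,
        grid=kspace.grid,
        is_noisy=True,
        seed=seed_int,
    )


def ifft_reconstruct(kspace: KSpaceData, spec: PhantomSpec | None = None) -> PhantomImage:
    """Reference reconstruction: DC-centered inverse FFT with amplitude scaling.

    Returns the complex image (Riemann sum of the inverse Fourier
    integral, ``delta_k**2`` absorbed into the scale) together with its
    magnitude.
    """
    v = np.asarray(kspace.values)
    if v.ndim != 2 or v.shape[0] != v.shape[1] or v.size == 0:
        raise ValueError("k-space must be a non-empty square 2-D array")
    grid = kspace.grid
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(v)))
    img = img * (grid.matrix_size**2 / grid.fov_mm**2)
    return PhantomImage(complex_image=img, grid=grid, spec=spec)


def _check_contained(disk: DiskSpec, fov_mm: float) -> None:
    if abs(disk.xc_mm) + disk.radius_mm > fov_mm / 2 or abs(disk.yc_mm) + disk.radius_mm > fov_mm / 2:
        raise LayoutError(
            f"disk (R={disk.radius_mm} mm at ({disk.xc_mm}, {disk.yc_mm})) "
            f"not contained in FOV {fov_mm} mm"
        )


def build_disk_phantom(
    fov_mm: float = 240.0,
    matrix_size: int = 128,
    radius_mm: float = 95.0,
    intensity: float = 0.5,
    sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Single centered disk used for geometry, uniformity, ghosting, sharpness, SNR."""
    grid = KSpaceGrid(fov_mm, matrix_size)
    disk = DiskSpec(radius_mm=radius_mm, intensity=intensity)
    _check_contained(disk, fov_mm)
    return PhantomSpec(
        kind="disk",
        disks=(disk,),
        grid=grid,
        noise_sigma=sigma,
        seed=seed,
        layout={"radius_mm": radius_mm, "intensity": intensity},
    )


# Resolution phantom layout -------------------------------------------------
#
# For each disk radius r and each direction, a block of 4 rows x 4 identical
# disks.  In-row center-to-center spacing is 4r (two diameters, ACR-style);
# a noiseless reconstruction resolves every default block — the finite
# 4-disk aperture is not band-limited like an infinite grating — so
# failures are noise-limited.  Row pitch is 4r and row j is shifted
# laterally by j*r/2 to sweep sub-pixel phases (partial-volume averaging).
# "Horizontal" blocks vary disk position along x within each row and
# measure resolution along x; "vertical" blocks are the transposed layout.

_BLOCK_X = {"x": -55.0, "y": 55.0}
_BLOCK_Y = (-75.0, -25.0, 25.0, 75.0)


def build_resolution_phantom(
    fov_mm: float = 240.0,
    matrix_size: int = 128,
    radii_mm: Sequence[float] = (0.8, 0.9, 1.0, 1.1),
    intensity: float = 0.5,
    sigma: float = 0.0,
    seed: int = 0,
    spacing_factor: float = 4.0,
    n_per_row: int = 4,
    n_rows: int = 4,
) -> PhantomSpec:
    """Directional disk-array phantom; radius r probes resolution 2r (mm)."""
    if len(radii_mm) > len(_BLOCK_Y):
        raise LayoutError("at most 4 radii fit the default block layout")
    grid = KSpaceGrid(fov_mm, matrix_size)
    disks: list[DiskSpec] = []
    blocks: list[dict] = []
    for bi, r in enumerate(radii_mm):
        pitch = spacing_factor * r
        for direction in ("x", "y"):
            bx, by = _BLOCK_X[direction], _BLOCK_Y[bi]
            rows = []
            for j in range(n_rows):
                centers = []
                for i in range(n_per_row):
                    along = (i - (n_per_row - 1) / 2) * pitch + j * r / 2
                    across = (j - (n_rows - 1) / 2) * pitch
                    if direction == "x":
                        x, y = bx + along, by + across
                    else:
                        x, y = bx + across, by + along
                    disks.append(DiskSpec(radius_mm=r, intensity=intensity, xc_mm=x, yc_mm=y))
                    centers.append([x, y])
                line = centers[0][1] if direction == "x" else centers[0][0]
                rows.append({"line_mm": line, "centers_mm": centers})
            blocks.append({"radius_mm": r, "direction": direction, "rows": rows})
    for d in disks:
        _check_contained(d, fov_mm)
    _check_no_overlap(disks)
    return PhantomSpec(
        kind="resolution",
        disks=tuple(disks),
        grid=grid,
        noise_sigma=sigma,
        seed=seed,
        layout={"radii_mm": list(radii_mm), "blocks": blocks, "intensity": intensity},
    )


def _check_no_overlap(disks: Sequence[DiskSpec], clearance_mm: float = 0.0) -> None:
    centers = np.array([[d.xc_mm, d.yc_mm] for d in disks])
    radii = np.array([d.radius_mm for d in disks])
    for i in range(len(disks)):
        dist = np.hypot(*(centers[i + 1:] - centers[i]).T)
        if np.any(dist < radii[i + 1:] + radii[i] + clearance_mm):
            raise LayoutError(f"disks overlap or violate {clearance_mm} mm clearance")


def build_lowcontrast_phantom(
    fov_mm: float = 240.0,
    matrix_size: int = 128,
    n_spokes: int = 10,
    disks_per_spoke: int = 3,
    radii_range_mm: tuple[float, float] = (0.75, 3.5),
    contrast: float = 0.2,
    background_radius_mm: float = 95.0,
    background_intensity: float = 0.5,
    spoke_distances_mm: Sequence[float] = (20.0, 40.0, 60.0),
    sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Background disk plus spokes of small hyper-intense disks.

    ``contrast`` is the relative intensity of the small disks against the
    background: the superimposed disks carry additive intensity
    ``contrast * background_intensity`` so their interior reconstructs to
    ``background_intensity * (1 + contrast)``.  Spoke ``s`` sits at angle
    ``360*s/n_spokes`` degrees and carries ``disks_per_spoke`` disks of a
    common radius; per-spoke radii are evenly spaced over
    ``radii_range_mm``, decreasing from spoke 0.  Disk centers are
    snapped to the nearest pixel center so that the pixel-centered
    detection templates see the same sub-pixel geometry as the
    calibration patches.
    """
    if len(spoke_distances_mm) != disks_per_spoke:
        raise LayoutError("need one radial distance per disk on a spoke")
    grid = KSpaceGrid(fov_mm, matrix_size)
    background = DiskSpec(radius_mm=background_radius_mm, intensity=background_intensity)
    _check_contained(background, fov_mm)
    spoke_radii = np.linspace(radii_range_mm[1], radii_range_mm[0], n_spokes)
    disks: list[DiskSpec] = [background]
    spokes: list[dict] = []
    for s, r in enumerate(spoke_radii):
        theta = 2.0 * np.pi * s / n_spokes
        centers = []
        for dist in spoke_distances_mm:
            px = grid.pixel_mm
            x = round(dist * np.cos(theta) / px) * px
            y = round(dist * np.sin(theta) / px) * px
            if np.hypot(x, y) + r > background_radius_mm:
                raise LayoutError(
                    f"spoke disk (R={r:.3f} at distance {dist}) extends beyond background disk"
                )
            disks.append(
                DiskSpec(radius_mm=float(r), intensity=contrast * background_intensity,
                         xc_mm=float(x), yc_mm=float(y))
            )
            centers.append([float(x), float(y)])
        spokes.append({"spoke": s, "radius_mm": float(r), "centers_mm": centers})
    _check_no_overlap(disks[1:], clearance_mm=2.0)
    return PhantomSpec(
        kind="low_contrast",
        disks=tuple(disks),
        grid=grid,
        noise_sigma=sigma,
        seed=seed,
        layout={
            "n_spokes": n_spokes,
            "disks_per_spoke": disks_per_spoke,
            "contrast": contrast,
            "background_radius_mm": background_radius_mm,
            "background_intensity": background_intensity,
            "spoke_distances_mm": list(spoke_distances_mm),
            "spokes": spokes,
        },
    )


def realization_rng(master_seed: int, *stream: int | str) -> np.random.Generator:
    """Deterministic per-realization substream from one master seed.

    Each distinct ``stream`` tuple (e.g. phantom kind index, realization
    index) yields an independent, reproducible generator, so realization k
    can be regenerated in isolation.
    """
    key = [master_seed] + [
        s if isinstance(s, (int, np.integer)) else int.from_bytes(str(s).encode(), "little") % (2**31)
        for s in stream
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def realize_kspace(
    spec: PhantomSpec,
    realization: int = 0,
    noiseless_kspace: KSpaceData | None = None,
) -> KSpaceData:
    """One (noisy) k-space realization of a phantom.

    The noiseless compound spectrum may be passed in to amortize its
    construction across realizations of the same spec.
    """
    if noiseless_kspace is None:
        noiseless_kspace = compound_kspace(spec.grid, spec.disks)
    if spec.noise_sigma > 0:
        rng = realization_rng(spec.seed, realization)
        return add_complex_noise(noiseless_kspace, spec.noise_sigma, rng)
    return noiseless_kspace


def realize(
    spec: PhantomSpec,
    realization: int = 0,
    noiseless_kspace: KSpaceData | None = None,
) -> tuple[KSpaceData, PhantomImage]:
    """Generate one noisy realization and its reference (iFFT) image."""
    ks = realize_kspace(spec, realization, noiseless_kspace)
    return ks, ifft_reconstruct(ks, spec=spec)
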
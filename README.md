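# droiq — digital reference-object phantoms and automated MR image-quality metrics

`droiq` benchmarks MRI reconstruction algorithms with *digital* image-quality
phantoms instead of conventional fidelity scores (SSIM/PSNR/RMSE), which miss
clinically relevant properties such as resolution, uniformity and low-contrast
detectability.  It is aimed at developers of reconstruction methods — in
particular machine-learning reconstructions — who need large, noise-controlled,
ground-truth-exact test sets and fully automated ACR/NEMA-style evaluation.

## The model

Test objects are unions of uniform disks defined in **continuous k-space**.  A
disk of radius R, intensity I and center (x_c, y_c) has the exact 2-D Fourier
transform

```
F(k_x, k_y) = Jinc(k_r | R) · I · exp(−2πi (x_c k_x + y_c k_y)),
Jinc(k_r | R) = 2πR² J₁(2πR k_r) / (2πR k_r),      k_r = √(k_x² + k_y²),
```

with J₁ the first-order Bessel function.  Compound phantoms are sums of disk
spectra.  The continuous spectrum is sampled on a DC-centered N×N grid with
spacing δk = 1/FOV, complex Gaussian noise ψ(0, σ) is added per sample, and the
reference image is the scaled inverse FFT — mimicking an MR acquisition of a
continuous object, so the digital object has no rasterization error.  Noise is
calibrated so that σ is the per-channel image-domain standard deviation and a
disk of intensity I has designed SNR = I/σ (defaults I = 0.5 with σ ∈
{0.04, 0.02} → SNR ∈ {12.5, 25}).

Three phantom types (FOV 240 mm, matrix 128, pixel 1.875 mm by default):

* **disk** — one centered disk, R = 95 mm: geometric accuracy (maximum
  percentage radius error of the region-grown equivalent ellipse), percent
  intensity uniformity (`100·(1 − (I_max−I_min)/(I_max+I_min))` after NEMA 3×3
  low-pass filtering inside the 5-px-eroded disk), ghosting ratio
  (`|(top+bottom) − (left+right)| / (2·disk)` over four N/2 × N/16 background
  rectangles), edge sharpness (FWHM Γ of a Lorentzian fitted to the derivative
  of the radial edge-spread function), and NEMA difference-image SNR
  (`√2 · mean / std(difference)` over two acquisitions).
* **resolution** — 4×4 arrays of small disks (radii 0.8–1.1 mm → resolutions
  1.6–2.2 mm) per direction; a resolution is achieved when four distinct peaks
  (Otsu threshold, two-radii separation) appear in at least one row.
* **low_contrast** — 10 spokes × 3 disks (radii 0.75–3.5 mm, contrast 0.2)
  on the large background disk; each disk is tested by sliding-window Pearson
  correlation against its noiseless template with a threshold calibrated on
  100 disk-present / 100 disk-absent simulated patches (classification
  accuracy < 0.70 ⇒ the disk size is undetectable); the metric is the number
  of spokes whose disks are all detected.

Any reconstruction can be plugged in (`k-space → image`); the built-in
reference is the inverse FFT, and a variable-density Cartesian undersampling
mask (full center, zero-filled outer lines) is provided for stress tests.

## Worked example

```python
from droiq import (build_disk_phantom, realize, detect_disk, geometric_accuracy,
                   intensity_uniformity, ghosting_ratio, build_ghosting_rois,
                   extract_esf, fit_lorentzian, snr_difference)
from droiq.phantoms import compound_kspace

spec = build_disk_phantom(sigma=0.04, seed=0)          # designed SNR = 12.5
noiseless = compound_kspace(spec.grid, spec.disks)
_, img1 = realize(spec, 0, noiseless)
_, img2 = realize(spec, 1, noiseless)

ellipse = detect_disk(img1)
print(f"detected radii      : {ellipse.r_major_mm:.2f} / {ellipse.r_minor_mm:.2f} mm")
print(f"geometric accuracy  : {geometric_accuracy(ellipse, 95.0):.3f} %")
print(f"intensity uniformity: {intensity_uniformity(img1, ellipse):.1f} %")
print(f"ghosting ratio      : {ghosting_ratio(img1, build_ghosting_rois(img1, ellipse)):.4f}")
print(f"sharpness (FWHM)    : {fit_lorentzian(extract_esf(img1)).fwhm_mm:.3f} mm")
print(f"difference SNR      : {snr_difference(img1, img2, ellipse):.1f}")
```

prints

```
detected radii      : 95.07 / 94.98 mm
geometric accuracy  : 0.076 %
intensity uniformity: 88.1 %
ghosting ratio      : 0.0025
sharpness (FWHM)    : 0.874 mm
difference SNR      : 12.6
```

i.e. for this single σ = 0.04 realization the detected disk radii are within
a tenth of a percent of the designed 95 mm, the uniformity and ghosting are at
the level expected for SNR 12.5, the edge FWHM is about half a pixel, and the
two-acquisition SNR measurement recovers the designed I/σ = 12.5.

The batch interface aggregates such values over hundreds of seeded
realizations into a mean ± std summary per phantom type and noise level
(`droiq run --report out/`, or `run_evaluation(EvalConfig(...))` from Python);
`droiq generate` / `droiq evaluate` exchange HDF5 stacks so external
reconstructions can be evaluated offline.

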
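# Methods

## Phantom model

All test objects are unions of uniform disks specified in physical units
(mm) and defined directly in continuous 2-D k-space through the analytic
transform of a disk, `Jinc(k_r|R)·I·exp(−2πi(x_c k_x + y_c k_y))`.
Compound objects are sums of disk spectra (Fourier linearity).  Because
the object lives in the continuous frequency domain, the discrete image
it produces carries the genuine band-limitation of an MR acquisition
(Gibbs ringing at edges, partial-volume averaging of sub-pixel objects)
rather than rasterization artifacts.

### Discretization and amplitude convention

The spectrum is sampled on a DC-centered N×N grid with spacing
δk = 1/FOV (DC at index N//2; N must be even).  The image is the Riemann
sum of the inverse Fourier integral,

    img = ifft2(samples) · N² / FOV²,

with `ifftshift/fftshift` applied around the transform.  Image pixel m
sits at (m − N/2)·FOV/N, so the FOV center falls on pixel N//2.  Under
this convention a noiseless disk of intensity I reconstructs to interior
value I (verified to 0.005 % at the defaults); the periodization error
from sampling a non-compact spectrum is below 1 % for the default disk.

### Noise model

Acquisition noise is zero-mean complex Gaussian, i.i.d. per k-space
sample and *not* Hermitian-symmetrized, so magnitude images have a
Rician foreground and Rayleigh background.  The parameter σ is quoted in
the image domain: each of the real and imaginary channels of the
reconstructed complex image has standard deviation σ (k-space channel
std = σ·FOV²/N).  This makes the designed SNR of a disk simply I/σ and
makes the two-acquisition difference SNR measurement, √2·mean/std(diff),
recover I/σ directly: the difference of two magnitude images has std
√2σ in the disk interior.  Defaults σ ∈ {0.04, 0.02} with I = 0.5 give
SNR ∈ {12.5, 25}.

### Seeding

One master seed per study.  Per-(phantom, noise-level) spec seeds and
per-realization noise streams are derived through `SeedSequence` keys,
so realization k is reproducible in isolation and two runs with the same
configuration are bit-identical.

## Phantom layouts

Parameters fixed by the study conditions: FOV 240 mm, N = 128 (pixel
1.875 mm), disk intensity 0.5, disk-phantom radius 95 mm, resolution
radii 0.8/0.9/1.0/1.1 mm, low-contrast 10 spokes × 3 disks with radii
evenly spaced 0.75–3.5 mm and contrast ratio 0.2, 600 realizations per
phantom per noise level.

Layout details the design left open were fixed as follows:

* **Resolution blocks.**  Per radius r and per direction, 4 rows of 4
  identical disks; in-row center-to-center spacing 4r (two diameters),
  row pitch 4r, row j shifted laterally by j·r/2 to sweep sub-pixel
  phases.  Blocks are tiled on a 2 (direction) × 4 (radius) grid at
  x = ∓55 mm, y ∈ {−75, −25, 25, 75} mm, leaving >10 mm margins.
  Although a 4r grating at r = 0.8 mm lies beyond the k-space cutoff
  (64/240 cyc/mm), a finite 4-disk row is not band-limited like an
  infinite grating and all default blocks resolve noiselessly; failures
  are noise-limited, which is the intended operating regime.
* **Low-contrast spokes.**  The spokes are superimposed on the large
  95 mm background disk (ACR-style), at angles 360°·s/10 and radial
  distances 20/40/60 mm; per-spoke radius decreases from 3.5 mm (spoke
  0) to 0.75 mm.  With a small dedicated background disk (~40 mm) the
  10×10-pixel detection patches would contain the background's Gibbs
  edge and neighbouring-disk ringing, which caps even noiseless template
  correlations near 0.6 and destroys detectability; the large background
  keeps every patch in clean interior.  Edge-to-edge clearance between
  small disks is ≥ 2 mm everywhere.  Disk centers are snapped to the
  nearest pixel center so that the pixel-centered calibration patches
  and templates see the same sub-pixel geometry as the phantom patches
  (sharp sub-pixel disks lose most of their correlation under half-pixel
  misalignment, which would bias detection against the phantom).
  Small disks are hyper-intense: additive intensity contrast ×
  background (0.1), i.e. interior value 0.6 on a 0.5 background.

## Metrics

* **Disk detection** (shared by several metrics): connected component
  (4-connectivity) of pixels above half the robust foreground level
  (median of the central 5×5 patch), seeded at the image center;
  equivalent-ellipse semi-axes from second central moments
  (sub-pixel, deterministic).  Noiseless bias ≈ 0.025 % at the defaults.
* **Geometric accuracy**: 100·max(|R_major−R_gt|, |R_minor−R_gt|)/R_gt.
* **Intensity uniformity**: disk mask eroded with a radius-5 disk
  structuring element; image filtered with the NEMA nine-point binomial
  kernel [[1,2,1],[2,4,2],[1,2,1]]/16 (reflect boundaries); extrema
  taken inside the eroded ROI.  The binomial kernel (rather than a
  uniform 1/9 box) is the NEMA standard nine-point low-pass.
* **Ghosting**: four N/2 × N/16 rectangles centered 7N/16 pixels from
  the *designed* disk center (decoupled from the detected centroid);
  numerator taken as an absolute value.
* **Sharpness**: the distance of every pixel to the designed center
  gives a naturally oversampled radial ESF; pixels in the window
  R ± 8 px are bin-averaged onto a 1/10-pixel grid; for noisy images
  (σ > 0) the profile is replaced by a 4-parameter logistic fit before
  the central-difference derivative is fitted with the 4-parameter
  Lorentzian (initialization: center at the extremum, width from the
  half-maximum crossings, amplitude from the peak area, offset 0;
  Γ bounded positive).  Γ depends mildly on the radial window (≈ 0.94 mm
  at ±4 px to ≈ 0.90 mm at ±16 px for σ = 0.02 defaults); the window is
  fixed at ±8 px for fit stability and is part of the metric definition.
* **Difference SNR**: √2·mean(img1)/std(img1−img2) over the eroded disk
  ROI; realizations 2k and 2k+1 form pair k.
* **Resolution**: per row, the pixel profile along the designed row line
  (one-pitch margin) is searched for local maxima above the profile's
  Otsu threshold with minimum separation 2r; a radius is achieved when
  exactly four peaks appear in at least one of its rows; the reported
  value per direction is the smallest achieved 2r, with a not-resolved
  sentinel (NaN) otherwise.
* **Low-contrast detectability**: per disk, the 10×10 patch at the
  designed center is compared to the noiseless same-radius template by
  Pearson correlation over the overlap at all shifts within ±3 pixels;
  the maximum is compared to a per-(radius, σ, contrast) threshold.
  Thresholds are calibrated on 100 disk-present and 100 disk-absent
  simulated patches rendered through the same k-space pipeline
  (present: centered disk on the background; absent: background only);
  candidate thresholds are midpoints of consecutive sorted scores, ties
  broken toward the higher threshold; best accuracy < 0.70 marks the
  disk size undetectable outright.  Thresholds are cached per noise
  level and reused across realizations.

## Batch pipeline

Metric routing is fixed (disk → geometry/uniformity/ghosting/sharpness/
SNR; resolution → directional resolution; low-contrast → visible
spokes).  Per-realization metric failures become error rows; the batch
always completes.  Summaries are mean ± sample std per (phantom, σ,
metric) with not-resolved/failed counts reported separately.  The
undersampling utility keeps the central 30 % of phase-encode lines
(horizontal axis) and draws the remainder without replacement with
Gaussian-in-offset weights (scale N/4) up to N/acceleration lines;
unsampled lines are zero-filled.

## What the generator does and does not emulate

The phantoms emulate band-limited Cartesian single-coil acquisitions
with additive complex Gaussian noise: Gibbs ringing, Rician magnitude
statistics, partial-volume effects and aliasing under undersampling are
all physically faithful.  They do not model coil sensitivities,
multi-coil combination, field inhomogeneity, relaxation contrast, 3-D
geometry or anthropomorphic structure; conclusions about reconstruction
behaviour on such data require real acquisitions.  Passing the test
suite therefore demonstrates correctness of the analytic models and the
automated metrics under the stated acquisition model, not performance on
clinical data.

## Problem sizes

The full study (600 realizations per phantom per noise level) runs in
about a minute on one CPU and is what `scripts/acceptance.py` executes.
The test suite exercises a scaled 100-realization study for the
reference-statistics comparison and 50-realization grids for the
monotonicity properties; these sizes keep Monte-Carlo standard errors
well below the assertion tolerances.

## Known limitations

* Geometric accuracy at the defaults carries a ≈ 0.025 % noiseless
  detection bias (threshold/moment interaction at the pixelated edge),
  comparable to the metric's own noise-induced spread; alternative
  region-growing conventions shift the mean by a few hundredths of a
  percentage point.
* The sharpness Γ is a convention-dependent summary (radial window,
  sigmoid pre-fit); comparisons are meaningful within a fixed
  configuration.
* Low-contrast detectability is sensitive to the sliding-shift range:
  wider ranges inflate the maximum correlation of disk-absent patches,
  which lowers calibration accuracy and, through the 0.70 reliability
  floor, the visible-spoke count at high noise.  The default ±3 px
  range favors robustness to reconstruction-induced translations (a
  real failure mode of learned reconstructions) at the cost of
  high-noise sensitivity; detectability comparisons across noise levels
  should hold this convention fixed.
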
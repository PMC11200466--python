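"""Analytic k-space models, noise calibration and the reference reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import jn_zeros

from droiq.phantoms import (
    DiskSpec,
    KSpaceData,
    KSpaceGrid,
    add_complex_noise,
    build_disk_phantom,
    build_lowcontrast_phantom,
    build_resolution_phantom,
    compound_kspace,
    disk_kspace,
    ifft_reconstruct,
    jinc,
    realize,
)
from droiq.phantoms import LayoutError


class TestJinc:
    def test_dc_limit_unit_radius(self):
        assert jinc(0.0, 1.0) == pytest.approx(np.pi)

    def test_dc_limit_scales_with_radius_squared(self):
        assert jinc(0.0, 95.0) == pytest.approx(np.pi * 95.0**2)

    def test_zero_at_first_bessel_root(self):
        # independent root table: first positive zero of J1 from scipy
        z1 = jn_zeros(1, 1)[0]  # ~3.8317
        kr = z1 / (2 * np.pi * 95.0)
        assert abs(jinc(kr, 95.0)) < 1e-6 * np.pi * 95.0**2

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            jinc(0.1, 0.0)


class TestDiskKspace:
    def test_centered_disk_is_real_with_dc_value(self, grid):
        ks = disk_kspace(grid, DiskSpec(95.0, 0.5))
        c = grid.matrix_size // 2
        assert np.abs(ks.values.imag).max() < 1e-12
        assert ks.values[c, c].real == pytest.approx(0.5 * np.pi * 95.0**2)

    def test_shift_theorem_modulus_and_phase(self, grid):
        centered = disk_kspace(grid, DiskSpec(30.0, 1.0))
        shifted = disk_kspace(grid, DiskSpec(30.0, 1.0, xc_mm=10.0))
        np.testing.assert_allclose(
            np.abs(shifted.values), np.abs(centered.values), rtol=1e-10, atol=1e-12
        )
        expected_phase = np.exp(-2j * np.pi * 10.0 * grid.kx())
        np.testing.assert_allclose(
            shifted.values, centered.values * expected_phase, rtol=1e-10, atol=1e-9
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        xc=st.floats(-20, 20),
        yc=st.floats(-20, 20),
        radius=st.floats(1.0, 90.0),
    )
    def test_shift_theorem_modulus_invariance(self, xc, yc, radius):
        grid = KSpaceGrid(240.0, 32)
        centered = disk_kspace(grid, DiskSpec(radius, 0.7))
        shifted = disk_kspace(grid, DiskSpec(radius, 0.7, xc, yc))
        np.testing.assert_allclose(
            np.abs(shifted.values), np.abs(centered.values), rtol=1e-10, atol=1e-12
        )


class TestCompound:
    def test_single_disk_equals_disk_kspace(self, grid):
        d = DiskSpec(10.0, 0.4, 5.0, -3.0)
        np.testing.assert_array_equal(
            compound_kspace(grid, [d]).values, disk_kspace(grid, d).values
        )

    def test_two_colocated_disks_double(self, grid):
        d = DiskSpec(10.0, 0.4)
        np.testing.assert_allclose(
            compound_kspace(grid, [d, d]).values, 2 * disk_kspace(grid, d).values
        )

    def test_opposite_intensities_cancel(self, grid):
        a = DiskSpec(10.0, 0.4, 2.0, 2.0)
        b = DiskSpec(10.0, -0.4, 2.0, 2.0)
        assert np.abs(compound_kspace(grid, [a, b]).values).max() < 1e-12

    def test_empty_list_rejected(self, grid):
        with pytest.raises(ValueError):
            compound_kspace(grid, [])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(i1=st.floats(-1, 1), i2=st.floats(-1, 1))
    def test_linearity_in_intensity(self, i1, i2):
        grid = KSpaceGrid(240.0, 32)
        d1, d2 = DiskSpec(12.0, i1 or 0.1, 4.0, 0.0), DiskSpec(7.0, i2 or 0.1, -9.0, 3.0)
        total = compound_kspace(grid, [d1, d2]).values
        np.testing.assert_allclose(
            total, disk_kspace(grid, d1).values + disk_kspace(grid, d2).values
        )


class TestNoise:
    def test_sigma_zero_is_identity(self, grid):
        ks = disk_kspace(grid, DiskSpec(95.0, 0.5))
        out = add_complex_noise(ks, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, ks.values)

    def test_negative_sigma_rejected(self, grid):
        ks = disk_kspace(grid, DiskSpec(95.0, 0.5))
        with pytest.raises(ValueError):
            add_complex_noise(ks, -0.1, seed=1)

    def test_same_seed_same_noise(self, grid):
        ks = disk_kspace(grid, DiskSpec(95.0, 0.5))
        a = add_complex_noise(ks, 0.04, seed=7)
        b = add_complex_noise(ks, 0.04, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_image_domain_noise_calibration(self, grid):
        """Per-channel image noise std equals sigma within 3 MC standard errors.

        With each k-space channel fed N(0, sigma*FOV^2/N) noise, the
        reconstructed complex image has per-channel std sigma, so the
        designed SNR of a disk of intensity I is I/sigma.
        """
        sigma = 0.04
        zeros = KSpaceData(np.zeros((128, 128), complex), grid)
        samples = []
        for k in range(100):
            img = ifft_reconstruct(add_complex_noise(zeros, sigma, seed=1000 + k))
            samples.append(img.complex_image.real.std(ddof=1))
            samples.append(img.complex_image.imag.std(ddof=1))
        mean_std = np.mean(samples)
        mc_se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(mean_std - sigma) < 3 * mc_se


class TestIfftReconstruct:
    def test_zero_kspace_gives_zero_image(self, grid):
        img = ifft_reconstruct(KSpaceData(np.zeros((128, 128), complex), grid))
        assert np.abs(img.magnitude).max() == 0.0

    def test_centered_disk_image_is_flip_symmetric(self, noiseless_disk_image):
        m = noiseless_disk_image.magnitude
        # pixel m=0 has no mirror partner on an even grid; compare the rest
        np.testing.assert_allclose(m[1:, 1:], m[1:, 1:][::-1, :], atol=1e-12)
        np.testing.assert_allclose(m[1:, 1:], m[1:, 1:][:, ::-1], atol=1e-12)

    def test_forward_fft_roundtrip(self, grid):
        ks = disk_kspace(grid, DiskSpec(40.0, 0.8, 7.0, -2.0))
        img = ifft_reconstruct(ks)
        n = grid.matrix_size
        back = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img.complex_image)))
        back *= grid.fov_mm**2 / n**2
        np.testing.assert_allclose(back, ks.values, atol=1e-9 * np.abs(ks.values).max())

    def test_rejects_nonsquare_or_misaligned(self, grid):
        with pytest.raises(ValueError):
            KSpaceData(np.zeros((4, 8), complex), grid)
        with pytest.raises(ValueError):
            KSpaceData(np.zeros((64, 64), complex), grid)  # wrong size for grid

    def test_amplitude_calibration_interior_intensity(
        self, noiseless_disk_image, interior_mask
    ):
        """Noiseless default disk reconstructs to interior intensity 0.5 within 1%."""
        interior_mean = noiseless_disk_image.magnitude[interior_mask].mean()
        assert interior_mean == pytest.approx(0.5, rel=0.01)


class TestBuilders:
    def test_disk_defaults_and_pixel_size(self):
        spec = build_disk_phantom()
        assert len(spec.disks) == 1
        assert spec.disks[0].radius_mm == 95.0
        assert spec.disks[0].intensity == 0.5
        assert spec.grid.pixel_mm == 240.0 / 128  # exactly 1.875
        assert spec.grid.pixel_mm == 1.875

    def test_disk_containment_error(self):
        with pytest.raises(LayoutError):
            build_disk_phantom(radius_mm=121.0)

    def test_resolution_layout_counts(self):
        spec = build_resolution_phantom()
        radii = spec.layout["radii_mm"]
        assert radii == [0.8, 0.9, 1.0, 1.1]
        assert len(spec.disks) == len(radii) * 2 * 16
        for block in spec.layout["blocks"]:
            assert len(block["rows"]) == 4
            for row in block["rows"]:
                assert len(row["centers_mm"]) == 4
        # radius r probes resolution 2r
        assert sorted({2 * b["radius_mm"] for b in spec.layout["blocks"]}) == [
            1.6, 1.8, 2.0, 2.2,
        ]

    def test_lowcontrast_layout(self):
        spec = build_lowcontrast_phantom()
        assert len(spec.disks) == 1 + 30
        background, *small = spec.disks
        assert background.radius_mm == 95.0
        # additive intensity of the small disks realises the 0.2 contrast ratio
        assert all(d.intensity == pytest.approx(0.2 * 0.5) for d in small)
        spoke_radii = [s["radius_mm"] for s in spec.layout["spokes"]]
        np.testing.assert_allclose(sorted(spoke_radii), np.linspace(0.75, 3.5, 10))
        assert all(len(s["centers_mm"]) == 3 for s in spec.layout["spokes"])

    def test_odd_matrix_rejected(self):
        with pytest.raises(ValueError):
            KSpaceGrid(240.0, 127)


class TestReproducibility:
    def test_identical_spec_bitwise_identical_output(self):
        spec = build_disk_phantom(sigma=0.04, seed=42)
        ks1, img1 = realize(spec, 3)
        ks2, img2 = realize(build_disk_phantom(sigma=0.04, seed=42), 3)
        np.testing.assert_array_equal(ks1.values, ks2.values)
        np.testing.assert_array_equal(img1.magnitude, img2.magnitude)

    def test_different_realizations_differ(self):
        spec = build_disk_phantom(sigma=0.04, seed=42)
        ks1, _ = realize(spec, 0)
        ks2, _ = realize(spec, 1)
        assert not np.array_equal(ks1.values, ks2.values)
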
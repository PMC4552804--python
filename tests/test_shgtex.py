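"""Fourier-ellipse directionality: FT oracle, thresholding, moments, tiling."""

import numpy as np
import pytest

from cervimetry.synth import FibreImage, FibreParams, simulate_fibre_image
from cervimetry.shgtex import (ROIWindow, compute_ft, threshold_ft,
                               ellipse_from_mask, directionality_R,
                               max10_intensity, tile_rois, stitch_tiles)


def dft_oracle(image):
    """Direct double-sum DFT magnitude, zero frequency at the array centre."""
    image = np.asarray(image, float)
    n0, n1 = image.shape
    out = np.zeros((n0, n1), complex)
    j0, j1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    for k0 in range(n0):
        for k1 in range(n1):
            out[k0, k1] = np.sum(
                image * np.exp(-2j * np.pi * (k0 * j0 / n0 + k1 * j1 / n1)))
    return np.abs(np.roll(np.roll(out, n0 // 2, axis=0), n1 // 2, axis=1))


class TestComputeFT:
    def test_matches_direct_dft(self, rng):
        image = rng.uniform(0, 100, (16, 16))
        ours = compute_ft(image)
        ref = dft_oracle(image)
        assert np.max(np.abs(ours - ref)) / np.max(ref) < 1e-9

    def test_constant_image_dc_only(self):
        spec = compute_ft(np.full((32, 32), 7.0))
        centre = spec[16, 16]
        assert centre == pytest.approx(7.0 * 32 * 32)
        spec[16, 16] = 0
        assert np.all(spec < 1e-8 * centre)

    def test_sinusoid_symmetric_peaks(self):
        n = 64
        x = np.arange(n)
        image = 10 + np.cos(2 * np.pi * 4 * x / n)[None, :] * np.ones((n, 1))
        spec = compute_ft(image)
        c = n // 2
        peaks = np.argsort(spec.ravel())[::-1][:3]
        coords = {tuple(divmod(int(i), n)) for i in peaks}
        assert coords == {(c, c), (c, c - 4), (c, c + 4)}

    def test_parseval(self, rng):
        image = rng.normal(size=(24, 24))
        spec = compute_ft(image)
        assert np.sum(spec**2) == pytest.approx(image.size * np.sum(image**2))


class TestThresholdFT:
    def test_constant_image_single_pixel(self):
        mask = threshold_ft(compute_ft(np.full((32, 32), 3.0)))
        assert mask.sum() == 1 and mask[16, 16]

    def test_centre_always_in_mask(self, rng):
        for _ in range(5):
            spec = compute_ft(rng.uniform(0, 1, (20, 20)) + 0.1)
            assert threshold_ft(spec)[10, 10]

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            threshold_ft(compute_ft(np.zeros((16, 16))))

    def test_disconnected_peaks_excluded(self):
        spec = np.zeros((21, 21))
        spec[10, 10] = 1.0          # DC
        spec[10, 11] = 0.9          # connected
        spec[3, 3] = 0.95           # harmonic peak, disconnected
        mask = threshold_ft(spec)
        assert mask[10, 10] and mask[10, 11] and not mask[3, 3]

    def test_gaussian_level_set(self):
        # anisotropic Gaussian spectrum: the 80 % level set is an analytic
        # ellipse; the mask must match it within a 1-px boundary band
        n = 101
        k0, k1 = np.meshgrid(np.arange(n) - 50, np.arange(n) - 50,
                             indexing="ij")
        sig0, sig1 = 4.0, 12.0
        spec = np.exp(-0.5 * ((k0 / sig0) ** 2 + (k1 / sig1) ** 2))
        mask = threshold_ft(spec)
        level = np.sqrt(-2 * np.log(0.8))
        inner = ((k0 / sig0) ** 2 + (k1 / sig1) ** 2) <= (level - 1 / sig0) ** 2
        outer = ((k0 / sig0) ** 2 + (k1 / sig1) ** 2) <= (level + 1 / sig0) ** 2
        assert np.all(mask[inner])
        assert not np.any(mask & ~outer)


class TestEllipseFromMask:
    def test_filled_disk_isotropic(self):
        n = 61
        r0, c0 = np.meshgrid(np.arange(n) - 30, np.arange(n) - 30,
                             indexing="ij")
        ell = ellipse_from_mask(r0**2 + c0**2 <= 20**2)
        assert ell.R == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("a,b", [(11, 5), (25, 10), (40, 8)])
    def test_rectangle_axis_ratio(self, a, b):
        mask = np.zeros((a + 10, a + 10), bool)
        mask[2:2 + b, 2:2 + a] = True
        ell = ellipse_from_mask(mask)
        # with the 1/12 pixel-variance correction the ratio is exact
        assert ell.R == pytest.approx(b / a, rel=1e-9)
        assert ell.orientation == pytest.approx(0.0, abs=1e-6)

    def test_rotation_shifts_orientation_only(self):
        mask = np.zeros((40, 40), bool)
        mask[10:14, 5:35] = True
        base = ellipse_from_mask(mask)
        rot = ellipse_from_mask(np.rot90(mask))
        assert rot.R == pytest.approx(base.R, rel=1e-9)
        assert abs((rot.orientation - base.orientation) % 180) == pytest.approx(
            90.0, abs=1e-6)

    def test_single_pixel_degenerate(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert ellipse_from_mask(mask).R == pytest.approx(1.0)

    def test_against_regionprops(self, rng):
        # independent cross-check: for large regions the pixel-variance
        # correction is negligible and axis lengths agree with regionprops
        from skimage.measure import regionprops
        mask = np.zeros((120, 120), bool)
        rr, cc = np.meshgrid(np.arange(120) - 60.0, np.arange(120) - 60.0,
                             indexing="ij")
        mask[(rr / 45)**2 + (cc / 20)**2 <= 1] = True
        ours = ellipse_from_mask(mask)
        ref = regionprops(mask.astype(int))[0]
        assert ours.major_axis == pytest.approx(ref.axis_major_length, rel=5e-3)
        assert ours.minor_axis == pytest.approx(ref.axis_minor_length, rel=5e-3)


class TestDirectionalityR:
    def test_invariances(self, aligned_image):
        roi = tile_rois(aligned_image)[0]
        base = directionality_R(roi.pixels)
        scaled = directionality_R(roi.pixels * 3.7)
        rotated = directionality_R(np.rot90(roi.pixels))
        assert 0 < base.R <= 1
        assert scaled.R == pytest.approx(base.R, rel=1e-9)
        assert rotated.R == pytest.approx(base.R, rel=1e-6)

    def test_isotropic_noise_near_one(self, rng):
        values = [directionality_R(rng.uniform(50, 100, (180, 180))).R
                  for _ in range(5)]
        assert min(values) >= 0.8

    def test_aligned_below_disordered(self):
        from cervimetry.synth import ALIGNED_FIBRES, DISORDERED_FIBRES
        import dataclasses
        r_pairs = []
        for s in range(8):
            pair = []
            for preset in (ALIGNED_FIBRES, DISORDERED_FIBRES):
                p = dataclasses.replace(preset, mean_orientation=(s * 37) % 180)
                roi = tile_rois(simulate_fibre_image(p, seed=s))[0]
                pair.append(directionality_R(roi).R)
            r_pairs.append(pair)
        aligned, disordered = np.array(r_pairs).T
        assert aligned.mean() < disordered.mean()
        assert np.mean(aligned < disordered) >= 0.75


class TestIntensityAndTiling:
    def test_max10_matches_sort_oracle(self, rng):
        image = rng.uniform(0, 1000, (40, 40))
        assert max10_intensity(image) == pytest.approx(
            np.sort(image.ravel())[-10:].mean())

    def test_max10_exactly_ten_bright(self):
        image = np.zeros((10, 10))
        image.ravel()[:10] = 100.0
        assert max10_intensity(image) == 100.0
        assert max10_intensity(np.full((5, 5), 7.0)) == 7.0

    def test_max10_needs_ten_pixels(self):
        with pytest.raises(ValueError):
            max10_intensity(np.zeros((3, 3)))

    def test_tile_rois_counts(self):
        img300 = FibreImage(pixels=np.zeros((300, 300)), pixel_size=1 / 3)
        assert len(tile_rois(img300, 60.0)) == 1
        assert tile_rois(img300, 60.0)[0].side == 180
        img6000 = FibreImage(pixels=np.zeros((6000, 6000), np.uint8),
                             pixel_size=1 / 3)
        assert len(tile_rois(img6000, 60.0)) == 33 * 33

    def test_tile_single_window(self):
        img = FibreImage(pixels=np.zeros((180, 180)), pixel_size=1 / 3)
        rois = tile_rois(img, 60.0)
        assert len(rois) == 1 and rois[0].origin == (0, 0)


class TestStitching:
    def test_identity_single_tile(self, aligned_image):
        out = stitch_tiles([[aligned_image]], overlap_frac=0.1)
        np.testing.assert_allclose(out.pixels, aligned_image.pixels)

    def test_constant_tiles_blend_to_constant(self):
        tile = FibreImage(pixels=np.full((50, 50), 42.0), pixel_size=1.0)
        out = stitch_tiles([[tile, tile], [tile, tile]], overlap_frac=0.1)
        assert out.pixels.shape == (95, 95)
        np.testing.assert_allclose(out.pixels, 42.0)

    def test_cut_and_restitch(self, aligned_image):
        src = aligned_image.pixels[:100, :190]
        overlap = 10  # 10 % of the 100-px tile side
        left = FibreImage(pixels=src[:, :100], pixel_size=aligned_image.pixel_size)
        right = FibreImage(pixels=src[:, 90:190],
                           pixel_size=aligned_image.pixel_size)
        out = stitch_tiles([[left, right]], overlap_frac=overlap / 100)
        assert out.pixels.shape == src.shape
        assert np.max(np.abs(out.pixels - src)) <= 1.0

    def test_inconsistent_tiles_rejected(self):
        a = FibreImage(pixels=np.zeros((50, 50)), pixel_size=1.0)
        b = FibreImage(pixels=np.zeros((40, 40)), pixel_size=1.0)
        with pytest.raises(ValueError, match="inconsistent"):
            stitch_tiles([[a, b]])


class TestROIWindow:
    def test_window_bounds_checked(self, aligned_image):
        with pytest.raises(ValueError):
            ROIWindow(parent=aligned_image, origin=(200, 200), side=180)
        with pytest.raises(ValueError):
            ROIWindow(parent=aligned_image, origin=(0, 0), side=8)
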
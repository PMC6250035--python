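"""Parametric map estimators and bootstrap bandwidth selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from voxelhisto import (
    bin_image,
    bootstrap_error,
    estimate_map,
    gaussian_smooth,
    select_kernel,
    voronoi_load,
)
from voxelhisto.maps import FFTSmoother


def brute_force_smooth(image, sigma, truncate=4.0):
    """Direct O(n^2) convolution with the sampled truncated Gaussian."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kern = np.outer(k1, k1)
    h, w = image.shape
    out = np.zeros_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += image[ii, jj] * kern[di + r, dj + r]
            out[i, j] = acc
    return out


class TestBinImage:
    def test_direct_mean(self):
        assert np.allclose(bin_image(np.array([[1, 0], [0, 0]]), (2, 2)), [[0.25]])

    def test_identity_on_constants(self):
        assert np.allclose(bin_image(np.ones((12, 9)), (3, 3)), 1.0)

    def test_partial_boundary_windows_average_actual_counts(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        out = bin_image(img, (2, 2))
        assert out.shape == (3, 3)
        # last row/col windows are 1 voxel wide
        assert out[2, 2] == img[4, 4]
        assert out[0, 2] == img[0:2, 4].mean()

    def test_full_scale_shape(self):
        # 2560 = 142*18 + 4: 143 bins, last from 4-voxel partial windows
        out = bin_image(np.zeros((2560, 2560), dtype=np.uint8), (18, 18))
        assert out.shape == (143, 143)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger than image"):
            bin_image(np.zeros((4, 4)), (5, 5))

    def test_3d_window(self):
        vol = np.ones((4, 6, 6))
        assert bin_image(vol, (1, 3, 3)).shape == (4, 2, 2)

    @given(st.integers(1, 4), st.integers(1, 4), st.integers(0, 1000))
    def test_mean_conserved_when_window_divides(self, bh, bw, seed):
        r = np.random.default_rng(seed)
        img = r.random((bh * 3, bw * 5))
        out = bin_image(img, (bh, bw))
        assert np.isclose(out.mean(), img.mean(), atol=1e-12)


class TestGaussianSmooth:
    def test_matches_brute_force_convolution(self, rng):
        img = (rng.random((9, 9)) < 0.4).astype(float)
        out = gaussian_smooth(img, 1.0)
        assert np.abs(out - brute_force_smooth(img, 1.0)).max() < 1e-10

    def test_single_voxel_mass_conserved(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        assert abs(gaussian_smooth(img, 3.0).sum() - 1.0) < 1e-8

    def test_interior_of_constant_image_stays_one(self):
        out = gaussian_smooth(np.ones((64, 64)), 2.0)
        assert np.isclose(out[32, 32], 1.0)

    def test_mask_renormalization_keeps_constants_unbiased(self):
        img = np.ones((32, 32)) * 0.5
        mask = np.zeros((32, 32))
        mask[8:24, 8:24] = 1
        out = gaussian_smooth(img, 3.0, mask=mask)
        inside = out[mask > 0]
        assert np.allclose(inside, 0.5, atol=1e-10)
        assert np.all(out[mask == 0] == 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.ones((4, 4)), 0.0)


class TestFFTSmoother:
    @pytest.mark.parametrize("sigma", [0.8, 3.0, 9.0])
    def test_equivalent_to_spatial_filter(self, sigma, rng):
        imgs = [(rng.random((64, 48)) < 0.2).astype(np.uint8) for _ in range(3)]
        sm = FFTSmoother(imgs, max_sigma=9.0)
        stack = sm.smooth_stack(sigma)
        for i, img in enumerate(imgs):
            ref = ndimage.gaussian_filter(img.astype(float), sigma,
                                          mode="constant", truncate=4.0)
            assert np.abs(stack[i].reshape(64, 48) - ref).max() < 1e-5


class TestVoronoiLoad:
    def test_empty_image_all_zero(self):
        assert np.all(voronoi_load(np.zeros((32, 32), np.uint8)) == 0)

    def test_single_object_one_cell(self, rng):
        from voxelhisto import RadiusModel, render_disks

        img = render_disks(np.array([[100.0, 100.0]]), RadiusModel(7, 0),
                           (200, 200), rng)
        load = voronoi_load(img)
        assert np.allclose(load, 149 / 200**2)

    def test_two_objects_nearest_centroid_oracle(self):
        img = np.zeros((20, 31), np.uint8)
        img[4:7, 3:6] = 1        # 9 px object, centroid (5, 4)
        img[13:16, 22:27] = 1    # 15 px object, centroid (14, 24)
        load = voronoi_load(img)
        cents = np.array([[5.0, 4.0], [14.0, 24.0]])
        sizes = np.array([9.0, 15.0])
        ii, jj = np.mgrid[0:20, 0:31]
        d = np.stack([(ii - c[0]) ** 2 + (jj - c[1]) ** 2 for c in cents])
        nearest = np.argmin(d, axis=0)
        expected = np.empty((20, 31))
        for k in range(2):
            expected[nearest == k] = sizes[k] / (nearest == k).sum()
        assert np.allclose(load, expected)

    def test_total_mass_equals_foreground_count(self, rng):
        img = (rng.random((60, 60)) < 0.05).astype(np.uint8)
        if img.sum() == 0:
            img[5, 5] = 1
        assert np.isclose(voronoi_load(img).sum(), img.sum(), rtol=1e-10)


class TestEstimateMap:
    def test_binning_dispatch_is_exact(self, rng):
        img = (rng.random((36, 36)) < 0.3).astype(np.uint8)
        pm = estimate_map(img, "binning", (6, 6))
        assert np.array_equal(pm.grid, bin_image(img, (6, 6)))

    def test_missing_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            estimate_map(np.zeros((8, 8)), "gaussian_binning", (2, 2))

    def test_tiny_sigma_converges_to_binning(self, rng):
        img = (rng.random((36, 36)) < 0.3).astype(np.uint8)
        pm = estimate_map(img, "gaussian_binning", (6, 6), sigma=0.1)
        assert np.allclose(pm.grid, bin_image(img, (6, 6)), atol=1e-6)

    @pytest.mark.parametrize("estimator", ["binning", "voronoi_binning",
                                           "gaussian_binning"])
    def test_outputs_are_loads_in_unit_interval(self, estimator, rng):
        img = (rng.random((54, 54)) < 0.4).astype(np.uint8)
        pm = estimate_map(img, estimator, (18, 18), sigma=2.0)
        assert pm.grid.min() >= 0 and pm.grid.max() <= 1 + 1e-12


def direct_bootstrap_error(images, sigma, samples):
    """Literal evaluation: loop over bootstrap means and left-out images."""
    t = len(images)
    smoothed = [gaussian_smooth(np.asarray(im, float), sigma) for im in images]
    per_j = []
    for j in range(t):
        errs = []
        for s in samples:
            if j in s:
                continue
            mu = np.mean([smoothed[i] for i in s], axis=0)
            errs.append(np.mean((mu - np.asarray(images[j], float)) ** 2))
        if errs:
            per_j.append(np.mean(errs))
    return float(np.mean(per_j))


class TestBootstrapError:
    def test_all_zero_images_zero_error(self, rng):
        imgs = [np.zeros((6, 6)) for _ in range(4)]
        assert bootstrap_error(imgs, 2.0, n_bootstrap=50, rng=rng) == 0.0

    def test_exhaustive_two_individual_enumeration(self):
        # T=2 one-voxel images {0, 1}; all 4 possible bootstrap samples.
        imgs = [np.array([[0.0]]), np.array([[1.0]])]
        samples = np.array(list(itertools.product([0, 1], repeat=2)))
        sigma = 0.05  # negligible: the sampled kernel degenerates to identity
        got = bootstrap_error(imgs, sigma, samples=samples)
        # only (1,1) leaves out 0 and only (0,0) leaves out 1; both give
        # squared error 1, so the hand-computed value is 1.
        assert got == pytest.approx(1.0)
        assert got == pytest.approx(direct_bootstrap_error(imgs, sigma, samples))

    def test_matches_direct_enumeration_on_random_cohort(self, rng):
        imgs = [(rng.random((5, 7)) < 0.5).astype(float) for _ in range(4)]
        samples = rng.integers(0, 4, size=(30, 4))
        got = bootstrap_error(imgs, 1.3, samples=samples)
        want = direct_bootstrap_error(imgs, 1.3, samples)
        assert got == pytest.approx(want, rel=1e-12)

    def test_identical_images_reduce_to_smoothing_bias(self, rng):
        img = (rng.random((12, 12)) < 0.5).astype(float)
        imgs = [img.copy() for _ in range(5)]
        got = bootstrap_error(imgs, 2.0, n_bootstrap=40, rng=rng)
        bias = np.mean((gaussian_smooth(img, 2.0) - img) ** 2)
        assert got == pytest.approx(bias, rel=1e-10)

    def test_no_out_of_bag_samples_raises(self):
        imgs = [np.zeros((2, 2)), np.ones((2, 2))]
        samples = np.array([[0, 1]])  # contains every individual
        with pytest.raises(ValueError, match="out-of-bag"):
            bootstrap_error(imgs, 1.0, samples=samples)


class TestSelectKernel:
    def test_identical_constant_images_tie_break_to_smallest(self, rng):
        imgs = [np.zeros((8, 8)) for _ in range(4)]
        curve = select_kernel([imgs], sigmas=[1.0, 2.0, 4.0], n_bootstrap=30,
                              rng=rng)
        assert np.all(curve.errors == 0)
        assert curve.selected_sigma == 1.0

    def test_errors_shape_and_selection_member(self, rng):
        g1 = [(rng.random((20, 20)) < 0.3).astype(np.uint8) for _ in range(4)]
        g2 = [(rng.random((20, 20)) < 0.1).astype(np.uint8) for _ in range(4)]
        sig = [0.5, 1.0, 2.0, 4.0]
        curve = select_kernel([g1, g2], sigmas=sig, n_bootstrap=40, rng=rng)
        assert curve.errors.shape == (2, 4)
        assert curve.selected_sigma in sig
        assert np.all(curve.errors >= 0)

    def test_selection_minimizes_mean_curve(self, rng):
        g = [(rng.random((16, 16)) < 0.4).astype(np.uint8) for _ in range(5)]
        curve = select_kernel([g], sigmas=[0.5, 1, 2, 4, 8], n_bootstrap=60,
                              rng=rng)
        assert curve.selected_sigma == curve.sigmas[np.argmin(curve.mean_errors)]


class TestStride:
    def test_stride_subsamples_the_voxel_sum(self, rng):
        imgs = [(rng.random((10, 10)) < 0.5).astype(float) for _ in range(4)]
        samples = rng.integers(0, 4, size=(20, 4))
        full = bootstrap_error(imgs, 1.0, samples=samples)
        sub = bootstrap_error(imgs, 1.0, samples=samples, stride=4)
        # same order of magnitude, different voxel set
        assert sub == pytest.approx(full, rel=0.5)
        assert sub != full
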
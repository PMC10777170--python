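"""Focus stacking: convolution kernels, sharpness, plane selection."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from pradstack.ddb import DdbStack, ImageGrid
from pradstack.focus import (
    LAPLACIAN_KERNEL_5X5,
    FocusConfig,
    focus_stack,
    gaussian_blur,
    gaussian_kernel,
    laplacian,
    sharpness,
    smooth_depth_profiles,
)


def _dense_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force 2D convolution with symmetric-reflect padding."""
    k = kernel.shape[0] // 2
    padded = np.pad(image, k, mode="symmetric")
    out = np.zeros_like(image, dtype=np.float64)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            patch = padded[i:i + 2 * k + 1, j:j + 2 * k + 1]
            out[i, j] = np.sum(patch * kernel[::-1, ::-1])
    return out


def _stack(images, depths=None, counts=None, pixel=1.0):
    images = np.asarray(images, dtype=np.float32)
    n, rows, cols = images.shape
    if depths is None:
        depths = np.arange(n, dtype=float)
    if counts is None:
        counts = np.ones_like(images, dtype=np.int32)
    grid = ImageGrid(pixel, (cols * pixel, rows * pixel))
    return DdbStack(np.asarray(depths, float), images, counts, grid)


class TestGaussianBlur:
    def test_kernel_normalized(self):
        assert gaussian_kernel(5, 1.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_unchanged(self):
        img = np.full((12, 12), 7.25)
        assert np.allclose(gaussian_blur(img), 7.25, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = gaussian_blur(img)
        assert np.allclose(out[5:10, 5:10], gaussian_kernel(5, 1.0),
                           atol=1e-12)

    def test_ramp_matches_dense_convolution_oracle(self):
        img = np.add.outer(np.arange(7.0), 2.0 * np.arange(7.0))
        oracle = _dense_convolve(img, gaussian_kernel(5, 1.0))
        assert np.allclose(gaussian_blur(img), oracle, atol=1e-10)

    def test_masked_pixels_excluded(self):
        img = np.full((10, 10), 3.0)
        img[4, 4] = 1e6  # invalid value must not leak
        mask = np.ones((10, 10), dtype=bool)
        mask[4, 4] = False
        assert np.allclose(gaussian_blur(img, mask), 3.0, atol=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.ones((3, 3)))


class TestLaplacian:
    def test_kernel_is_zero_sum(self):
        assert LAPLACIAN_KERNEL_5X5.sum() == 0.0

    def test_constant_image_maps_to_zero(self):
        assert np.allclose(laplacian(np.full((9, 9), 42.0)), 0.0, atol=1e-10)

    def test_ramp_interior_zero(self):
        img = np.add.outer(3.0 * np.arange(11.0), -1.5 * np.arange(11.0))
        out = laplacian(img)
        assert np.allclose(out[2:-2, 2:-2], 0.0, atol=1e-9)

    def test_step_edge_matches_dense_oracle_and_antisymmetry(self):
        img = np.zeros((10, 12))
        img[:, 6:] = 1.0
        out = laplacian(img)
        oracle = _dense_convolve(img, LAPLACIAN_KERNEL_5X5)
        assert np.allclose(out, oracle, atol=1e-10)
        assert np.allclose(out[:, 4:6], -out[:, 7:5:-1], atol=1e-10)

    def test_nonzero_sum_kernel_rejected(self):
        with pytest.raises(ValueError):
            FocusConfig(laplacian_kernel=np.ones((5, 5)))


class TestSharpness:
    def test_constant_stack_is_flat(self):
        s = sharpness(_stack(np.full((3, 10, 10), 5.0)))
        assert np.allclose(s.values, 0.0, atol=1e-6)

    def test_sharpest_plane_wins_at_edge(self):
        """Planes hold the same edge at different Gaussian blurs; sharpness
        at the edge is maximal on the least blurred plane."""
        from scipy.ndimage import gaussian_filter
        base = np.zeros((20, 20))
        base[:, 10:] = 10.0
        planes = [gaussian_filter(base, s) for s in (2.0, 0.5, 3.0)]
        s = sharpness(_stack(planes))
        edge = s.values[:, 10, 9:11].mean(axis=1)
        assert np.argmax(edge) == 1

    def test_single_plane_stack(self):
        s = sharpness(_stack(np.random.default_rng(0).normal(size=(1, 8, 8))))
        assert s.values.shape[0] == 1


class TestSavitzkyGolay:
    def test_polynomial_profiles_unchanged(self):
        n = np.arange(31.0)
        profile = 2.0 + 0.1 * n - 0.01 * n ** 2 + 1e-3 * n ** 3
        stack = np.abs(profile)[:, None, None] * np.ones((1, 6, 6))
        s = sharpness(_stack(np.tile(profile[:, None, None], (1, 6, 6))))
        sm = smooth_depth_profiles(
            type(s)(stack.astype(np.float32), np.arange(31.0),
                    np.ones_like(stack, bool)), 11, 3)
        assert np.allclose(sm.values[5:-5], stack[5:-5], rtol=1e-4)

    def test_window_one_is_identity(self):
        s = sharpness(_stack(np.random.default_rng(1).normal(
            size=(5, 8, 8)) ** 2))
        sm = smooth_depth_profiles(s, 1, 3)
        assert np.array_equal(sm.values, s.values)

    def test_noisy_unimodal_argmax_recovered(self):
        """Savitzky-Golay smoothing keeps the argmax of a noisy unimodal
        profile within 2 planes of the true peak in >= 95% of trials."""
        rng = np.random.default_rng(11)
        n_trials, n_planes, true_peak = 1000, 41, 20.0
        x = np.arange(n_planes)
        clean = np.exp(-0.5 * ((x - true_peak) / 5.0) ** 2)
        hits = 0
        for _ in range(n_trials):
            noisy = clean + rng.normal(0, 0.15, n_planes)
            sm = savgol_filter(noisy, 11, 3)
            if abs(int(np.argmax(sm)) - true_peak) <= 2:
                hits += 1
        assert hits >= 950

    def test_invalid_window_rejected(self):
        s = sharpness(_stack(np.zeros((15, 8, 8))))
        with pytest.raises(ValueError):
            smooth_depth_profiles(s, 4, 3)
        with pytest.raises(ValueError):
            smooth_depth_profiles(s, 3, 5)
        with pytest.raises(ValueError):
            smooth_depth_profiles(s, 17, 3)


class TestFocusStack:
    def test_identical_planes_reproduce_image_and_front_depth(self):
        rng = np.random.default_rng(2)
        img = rng.normal(10.0, 1.0, (12, 12)).astype(np.float32)
        stack = _stack(np.stack([img] * 4), depths=[0.0, 1.0, 2.0, 3.0])
        res = focus_stack(stack, FocusConfig(savgol_window=1))
        assert np.array_equal(res.fs_image, img)
        assert np.all(res.focal_depth_map == 0.0)  # ties -> shallowest

    def test_single_plane_idempotent(self):
        img = np.random.default_rng(3).normal(size=(9, 9)).astype(np.float32)
        res = focus_stack(_stack(img[None]), FocusConfig(savgol_window=1))
        assert np.array_equal(res.fs_image, img)

    def test_blur_ladder_selects_sharp_plane(self):
        """Edge blurred with sigma {2, 0.5, 3} px: edge pixels select the
        middle plane, and FS values come from the raw stack."""
        from scipy.ndimage import gaussian_filter
        base = np.zeros((24, 24))
        base[:, 12:] = 10.0
        planes = [gaussian_filter(base, s) for s in (2.0, 0.5, 3.0)]
        stack = _stack(planes, depths=[0.0, 1.0, 2.0])
        res = focus_stack(stack, FocusConfig(savgol_window=1))
        edge_cols = slice(11, 13)
        assert np.all(res.focal_depth_map[8:16, edge_cols] == 1.0)
        sel = res.fs_image[8:16, edge_cols]
        assert np.allclose(sel, stack.images[1][8:16, edge_cols])

    def test_selection_property_on_random_stacks(self):
        """Every valid FS pixel value is an element of that pixel's raw
        depth profile."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            images = rng.normal(100.0, 5.0, (8, 10, 10)).astype(np.float32)
            counts = (rng.random((8, 10, 10)) > 0.2).astype(np.int32)
            images[counts == 0] = np.nan
            stack = _stack(images, counts=counts)
            res = focus_stack(stack, FocusConfig(savgol_window=5,
                                                 savgol_polyorder=2))
            for i in range(10):
                for j in range(10):
                    if res.valid[i, j]:
                        profile = stack.images[:, i, j]
                        assert res.fs_image[i, j] in profile[
                            np.isfinite(profile)]
                    else:
                        assert np.isnan(res.fs_image[i, j])

    def test_invalid_plane_falls_back_to_next_best(self):
        rng = np.random.default_rng(5)
        images = rng.normal(10.0, 0.1, (3, 8, 8)).astype(np.float32)
        images[1, :, 4:] += 5.0  # plane 1 sharpest at the step
        counts = np.ones((3, 8, 8), dtype=np.int32)
        counts[1, 4, 4] = 0  # but invalid at one pixel
        images[1, 4, 4] = np.nan
        stack = _stack(images)
        res = focus_stack(stack, FocusConfig(savgol_window=1))
        assert res.valid[4, 4]
        assert res.focal_depth_map[4, 4] != 1.0

    def test_brute_force_equivalence(self):
        """Bit-exact agreement with a direct per-pixel implementation of the
        argmax-of-|Laplacian| selection on random stacks."""
        rng = np.random.default_rng(6)
        cfg = FocusConfig(savgol_window=5, savgol_polyorder=3)
        for _ in range(3):
            images = rng.normal(200.0, 2.0, (8, 16, 16)).astype(np.float32)
            stack = _stack(images)
            res = focus_stack(stack, cfg)

            # oracle: per-plane sharpness, per-pixel 1D smoothing, explicit
            # python argmax with shallow tie-break and raw-stack sampling
            sharp = np.empty_like(images)
            for n in range(8):
                blurred = gaussian_blur(images[n], np.ones((16, 16), bool),
                                        cfg.gaussian_size, cfg.gaussian_sigma)
                sharp[n] = np.abs(laplacian(blurred, cfg.laplacian_kernel))
            for i in range(16):
                for j in range(16):
                    prof = np.maximum(
                        savgol_filter(sharp[:, i, j], 5, 3), 0.0)
                    best, best_val = 0, -np.inf
                    for n in range(8):
                        if prof[n] > best_val:
                            best, best_val = n, prof[n]
                    assert res.fs_image[i, j] == images[best, i, j]
                    assert res.focal_depth_map[i, j] == float(best)

    def test_all_invalid_pixel_marked_invalid(self):
        images = np.full((2, 8, 8), 5.0, dtype=np.float32)
        counts = np.ones((2, 8, 8), dtype=np.int32)
        counts[:, 3, 3] = 0
        images[:, 3, 3] = np.nan
        res = focus_stack(_stack(images, counts=counts),
                          FocusConfig(savgol_window=1))
        assert not res.valid[3, 3]
        assert np.isnan(res.fs_image[3, 3])
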
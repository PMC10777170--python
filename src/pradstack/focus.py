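"""Focus stacking of DDB image stacks.

Per pixel, the focal plane is the stack depth maximizing the local sharpness
measure |Laplacian(Gaussian-blurred image)|; the focus-stacked (FS) image
takes the raw DDB value at that plane:

    f_fs[i, j] = f^n*[i, j],  n* = argmax_n |lap(blur(f^n))[i, j]|

Sharpness-versus-depth profiles are smoothed per pixel with a Savitzky-Golay
filter before the argmax to suppress noise-driven plane selection. The FS
image samples the *raw* stack, so smoothing and blurring never touch the
reported WET values; the focal-depth map doubles as an estimate of each
feature's radiological depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .ddb import DdbStack

__all__ = ["FocusConfig", "SharpnessStack", "FocusResult", "gaussian_kernel",
           "LAPLACIAN_KERNEL_5X5", "gaussian_blur", "laplacian", "sharpness",
           "smooth_depth_profiles", "focus_stack"]


def gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Normalized ``size x size`` Gaussian kernel (truncated, sum 1)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and positive")
    x = np.arange(size) - size // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


#: Fixed 5x5 Laplacian-of-Gaussian-style kernel (zero-sum).
LAPLACIAN_KERNEL_5X5 = np.array(
    [
        [0, 0, 1, 0, 0],
        [0, 1, 2, 1, 0],
        [1, 2, -16, 2, 1],
        [0, 1, 2, 1, 0],
        [0, 0, 1, 0, 0],
    ],
    dtype=np.float64,
)


@dataclass
class FocusConfig:
    """Tunable parameters of the focus-stacking operator."""

    gaussian_size: int = 5
    gaussian_sigma: float = 1.0  # pixels
    laplacian_kernel: np.ndarray = field(
        default_factory=lambda: LAPLACIAN_KERNEL_5X5.copy())
    savgol_window: int = 11  # planes; 1 disables depth smoothing
    savgol_polyorder: int = 3

    def __post_init__(self) -> None:
        k = np.asarray(self.laplacian_kernel, dtype=np.float64)
        if abs(k.sum()) > 1e-9:
            raise ValueError("Laplacian kernel must be zero-sum")
        self.laplacian_kernel = k
        if self.savgol_window != 1:
            if self.savgol_window % 2 == 0 or self.savgol_window < 3:
                raise ValueError("savgol_window must be odd")
            if self.savgol_polyorder >= self.savgol_window:
                raise ValueError("savgol_polyorder must be < savgol_window")


@dataclass
class SharpnessStack:
    """|Laplacian| sharpness per (plane, pixel), same shape as the source
    stack; non-negative."""

    values: np.ndarray  # (n_planes, n_rows, n_cols)
    depths: np.ndarray
    valid: np.ndarray


@dataclass
class FocusResult:
    """Focus-stacked image with its per-pixel focal-depth map."""

    fs_image: np.ndarray  # WET mm, NaN where invalid
    focal_depth_map: np.ndarray  # mm, NaN where invalid
    max_sharpness_map: np.ndarray
    valid: np.ndarray
    depths: np.ndarray
    grid: object = None


def _check_image(image: np.ndarray, size: int) -> None:
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(image.shape) < size:
        raise ValueError("image smaller than the convolution kernel")


def gaussian_blur(image: np.ndarray, mask: np.ndarray | None = None,
                  size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """5x5 Gaussian blur with reflect padding and mask-weighted
    normalization.

    Invalid pixels (mask False) are excluded from the local average: the
    image is convolved with zeros at invalid pixels and renormalized by the
    convolved mask. A constant image is reproduced exactly.
    """
    _check_image(image, size)
    k = gaussian_kernel(size, sigma)
    if mask is None:
        return ndimage.convolve(np.asarray(image, dtype=np.float64), k,
                                mode="reflect")
    m = mask.astype(np.float64)
    filled = np.where(mask, image, 0.0).astype(np.float64)
    num = ndimage.convolve(filled, k, mode="reflect")
    den = ndimage.convolve(m, k, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def laplacian(image: np.ndarray,
              kernel: np.ndarray | None = None) -> np.ndarray:
    """Convolution with the fixed zero-sum 5x5 Laplacian kernel (reflect
    padding). Annihilates constant and affine images in the interior."""
    if kernel is None:
        kernel = LAPLACIAN_KERNEL_5X5
    _check_image(image, kernel.shape[0])
    return ndimage.convolve(np.asarray(image, dtype=np.float64), kernel,
                            mode="reflect")


def sharpness(stack: DdbStack, cfg: FocusConfig | None = None) -> SharpnessStack:
    """Per-plane sharpness |laplacian(gaussian_blur(f^n))|."""
    if cfg is None:
        cfg = FocusConfig()
    n = stack.n_planes
    out = np.empty_like(stack.images, dtype=np.float32)
    valid = stack.valid
    for i in range(n):
        blurred = gaussian_blur(stack.images[i], valid[i],
                                cfg.gaussian_size, cfg.gaussian_sigma)
        blurred = np.nan_to_num(blurred, nan=0.0)
        out[i] = np.abs(laplacian(blurred, cfg.laplacian_kernel))
    return SharpnessStack(out, stack.depths, valid)


def smooth_depth_profiles(s: SharpnessStack, window: int = 11,
                          polyorder: int = 3) -> SharpnessStack:
    """Savitzky-Golay smoothing of each pixel's sharpness-versus-depth
    profile; ``window = 1`` is the identity. Output clipped at 0."""
    if window == 1:
        return SharpnessStack(s.values.copy(), s.depths, s.valid)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window > s.values.shape[0]:
        raise ValueError("window exceeds the number of planes")
    sm = signal.savgol_filter(s.values, window, polyorder, axis=0)
    return SharpnessStack(np.maximum(sm, 0.0).astype(s.values.dtype),
                          s.depths, s.valid)


def focus_stack(stack: DdbStack, cfg: FocusConfig | None = None) -> FocusResult:
    """Collapse a DDB stack into the focus-stacked image.

    Per pixel: compute the (Savitzky-Golay smoothed) sharpness profile, take
    the argmax over planes restricted to planes where the pixel is valid
    (ties break toward the shallowest depth), and sample the raw stack value
    at that plane. A pixel invalid in every plane stays invalid.
    """
    if cfg is None:
        cfg = FocusConfig()
    if stack.n_planes < 1:
        raise ValueError("empty stack")
    sharp = sharpness(stack, cfg)
    if stack.n_planes >= cfg.savgol_window:
        sharp = smooth_depth_profiles(sharp, cfg.savgol_window,
                                      cfg.savgol_polyorder)
    score = np.where(sharp.valid, sharp.values, -np.inf)
    best = np.argmax(score, axis=0)  # first occurrence wins ties
    rows, cols = np.indices(best.shape)
    valid = sharp.valid.any(axis=0)
    fs = stack.images[best, rows, cols]
    fs = np.where(valid, fs, np.nan)
    depth_map = np.where(valid, stack.depths[best], np.nan)
    max_sharp = np.where(valid, sharp.values[best, rows, cols], np.nan)
    return FocusResult(fs, depth_map, max_sharp, valid, stack.depths,
                       stack.grid)
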
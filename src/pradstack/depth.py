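"""Feature radiological-depth estimation from the focal-depth map.

The binning depth at which a feature's edge is sharpest approximates the
feature's radiological depth. For a user-supplied pixel rectangle around an
edge, this module summarizes the per-pixel focal depths (median as the
headline estimator, interquartile range as the spread) and exposes the mean
|Laplacian|-versus-depth profile of the region. Only regions containing a
WET gradient carry depth information; homogeneous regions yield spreads
covering a large fraction of the depth range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .focus import FocusResult, SharpnessStack

__all__ = ["Roi", "DepthEstimate", "roi_depth_estimate",
           "laplacian_depth_profile", "cube_bottom_edge_roi"]


@dataclass(frozen=True)
class Roi:
    """Pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("empty ROI")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class DepthEstimate:
    """Summary of the focal depths inside an ROI."""

    roi: Roi
    depths: np.ndarray  # focal depth of each valid ROI pixel [mm]
    median_depth: float
    iqr: float
    profile_depths: np.ndarray | None = None
    profile_mean: np.ndarray | None = None
    profile_std: np.ndarray | None = None


def _check_roi(shape: tuple[int, int], roi: Roi) -> None:
    if roi.row0 < 0 or roi.col0 < 0 or roi.row1 > shape[0] or roi.col1 > shape[1]:
        raise ValueError("ROI extends outside the image")


def roi_depth_estimate(result: FocusResult, roi: Roi,
                       sharp: SharpnessStack | None = None) -> DepthEstimate:
    """Median/IQR of the per-pixel focal depths over a pixel rectangle.

    If a sharpness stack is supplied, the mean/std |Laplacian| depth profile
    of the region is attached to the estimate.
    """
    _check_roi(result.fs_image.shape, roi)
    rs, cs = roi.slices
    depths = result.focal_depth_map[rs, cs]
    mask = result.valid[rs, cs] & np.isfinite(depths)
    vals = depths[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no valid pixels")
    q25, med, q75 = np.percentile(vals, [25.0, 50.0, 75.0])
    est = DepthEstimate(roi, vals, float(med), float(q75 - q25))
    if sharp is not None:
        d, m, s = laplacian_depth_profile(sharp, roi)
        est.profile_depths, est.profile_mean, est.profile_std = d, m, s
    return est


def laplacian_depth_profile(s: SharpnessStack, roi: Roi):
    """Mean and std of the sharpness over ROI pixels, per depth plane."""
    _check_roi(s.values.shape[1:], roi)
    rs, cs = roi.slices
    block = s.values[:, rs, cs].reshape(s.values.shape[0], -1)
    vmask = s.valid[:, rs, cs].reshape(s.valid.shape[0], -1)
    if not vmask.any():
        raise ValueError("ROI contains no valid pixels")
    block = np.where(vmask, block, np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(block, axis=1)
        std = np.nanstd(block, axis=1)
    return s.depths.copy(), mean, std


def cube_bottom_edge_roi(grid, cube, n_t: int = 20, n_v: int = 4) -> Roi:
    """Pixel rectangle (default 20 x 4 pixels) straddling the bottom edge of
    a cube insert: centered horizontally on the cube, centered vertically on
    the lower (smallest-v) cube face."""
    v_edge = cube.center_v - cube.edge / 2.0
    half_t = n_t * grid.pixel_size / 2.0
    half_v = n_v * grid.pixel_size / 2.0
    rs, cs = grid.roi_slices(
        (cube.center_t - half_t + 1e-9, cube.center_t + half_t - 1e-9),
        (v_edge - half_v + 1e-9, v_edge + half_v - 1e-9))
    return Roi(rs.start, cs.start, rs.stop, cs.stop)
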
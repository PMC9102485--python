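"""Disparity-map post-processing: Gaussian hole filling, then median smoothing.

Dense matching still leaves holes — occlusions fail the consistency check,
and low-texture or specular pixels produce no reliable winner.  Holes are
filled by normalized convolution with a 2-D Gaussian point-spread function:
each invalid pixel becomes the Gaussian-weighted mean of the *valid* pixels
inside the kernel support, iterated until everything reachable is filled.
Measured (valid) disparities are never altered by the fill.  A median filter
then removes speckle — isolated wrong winners that survived the checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sgm import DisparityMap

__all__ = ["RefineParams", "gaussian_fill", "median_smooth"]


@dataclass(frozen=True)
class RefineParams:
    """Gaussian PSF width/extent, fill iteration cap, and median window."""

    gaussian_sigma_px: float = 2.0
    kernel_radius_px: int = 4
    max_fill_iterations: int = 10
    median_window: int = 5

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be > 0")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_fill(disp: DisparityMap, params: RefineParams | None = None,
                  smooth_all: bool = False) -> DisparityMap:
    """Fill invalid pixels by mask-normalized Gaussian convolution.

    Each pass replaces every invalid pixel whose kernel support contains at
    least one valid pixel with the normalized weighted mean of those valid
    values; passes repeat until the map is full or ``max_fill_iterations`` is
    reached.  Filled values are convex combinations of valid neighbors, so
    the output range never exceeds the valid input range.  With
    ``smooth_all`` the final map is additionally convolved everywhere
    (measured pixels included), matching a plain PSF-convolution reading.
    """
    params = params or RefineParams()
    valid = disp.valid & np.isfinite(disp.disparity)
    if not valid.any():
        raise ValueError("cannot fill a wholly invalid disparity map")
    kernel = _gaussian_kernel(params.gaussian_sigma_px, params.kernel_radius_px)
    values = np.where(valid, disp.disparity, 0.0)
    filled = values.copy()
    filled_mask = valid.copy()
    if not smooth_all and valid.all():
        return DisparityMap(disparity=disp.disparity.copy(), valid=valid, params=disp.params)
    for _ in range(params.max_fill_iterations):
        if filled_mask.all():
            break
        num = ndimage.convolve(np.where(filled_mask, filled, 0.0), kernel, mode="constant")
        den = ndimage.convolve(filled_mask.astype(float), kernel, mode="constant")
        reachable = ~filled_mask & (den > 1e-12)
        filled[reachable] = num[reachable] / den[reachable]
        filled_mask |= reachable
    out = np.where(filled_mask, filled, np.nan)
    if smooth_all:
        num = ndimage.convolve(np.where(filled_mask, filled, 0.0), kernel, mode="constant")
        den = ndimage.convolve(filled_mask.astype(float), kernel, mode="constant")
        out = np.where(filled_mask, num / np.maximum(den, 1e-12), np.nan)
    return DisparityMap(disparity=out, valid=filled_mask, params=disp.params)


def median_smooth(disp: DisparityMap, params: RefineParams | None = None) -> DisparityMap:
    """Median filter over ``median_window`` with edge-replicated borders.

    Removes single-pixel speckle while preserving step edges to within a
    pixel.  Remaining invalid (NaN) pixels are excluded from each window's
    median and stay invalid in the output.
    """
    params = params or RefineParams()
    d = disp.disparity
    if np.isnan(d).any():
        # NaN-aware median: generic_filter is slow, so fall back to it only
        # for the (rare) maps that still carry holes after filling.
        def nanmed(w):
            w = w[np.isfinite(w)]
            return np.median(w) if w.size else np.nan

        out = ndimage.generic_filter(d, nanmed, size=params.median_window, mode="nearest")
    else:
        out = ndimage.median_filter(d, size=params.median_window, mode="nearest")
    valid = disp.valid & np.isfinite(out)
    out = np.where(valid, out, np.nan)
    return DisparityMap(disparity=out, valid=valid, params=disp.params)
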
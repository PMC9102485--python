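"""Triangulation of a disparity map into an organized metric point cloud.

On a rectified rig with the world origin at the left optical center, a pixel
``(c, r)`` with disparity ``d`` px triangulates to

    z = b * f_px / d
    x = (c - cx) * z / f_px
    y = (r - cy) * z / f_px

(all mm).  The cloud is *organized*: a (rows, cols, 3) array aligned 1:1 with
the rectified left image, NaN where the disparity was invalid, so image-space
masks (tray, food) index straight into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rig import StereoRig
from .sgm import DisparityMap

__all__ = ["PointCloud", "disparity_to_depth", "triangulate_map"]


@dataclass
class PointCloud:
    """Organized (rows, cols, 3) xyz coordinates in mm; NaN where invalid."""

    points: np.ndarray
    rig: StereoRig | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.points).all(axis=-1)

    def valid_points(self) -> np.ndarray:
        """Flat (N, 3) array of the finite points."""
        return self.points[self.valid]


def disparity_to_depth(d, rig: StereoRig):
    """Depth z = b * f_px / d (mm) for disparity d (px); scalar or array.

    Scalar non-positive disparities raise (the point would sit at or beyond
    infinity); in arrays they propagate as NaN so callers can keep masks.
    """
    f_px = rig.focal_length_px
    if np.isscalar(d):
        if d <= 0:
            raise ValueError(f"disparity must be > 0, got {d}")
        return rig.baseline_mm * f_px / d
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = rig.baseline_mm * f_px / d
    return np.where(d > 0, z, np.nan)


def triangulate_map(disp: DisparityMap, rig: StereoRig) -> PointCloud:
    """Triangulate every valid pixel of a left-referenced disparity map."""
    if not rig.rectified:
        raise ValueError("triangulate_map requires a rectified rig")
    d = np.where(disp.valid, disp.disparity, np.nan)
    z = disparity_to_depth(d, rig)
    h, w = d.shape
    f_px = rig.focal_length_px
    cx, cy = rig.left.principal_point
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = (cols - cx) * z / f_px
    y = (rows - cy) * z / f_px
    return PointCloud(points=np.stack([x, y, z], axis=-1), rig=rig)
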
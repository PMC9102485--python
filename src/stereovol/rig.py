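"""Stereo rig model, rectification, and the spatial-resolution design calculator.

The rig is a fronto-parallel pinhole pair: two identical cameras separated by a
horizontal baseline ``b`` (mm), with the world origin at the left camera's
optical center, x to the right, y down, z toward the scene.  On a rectified rig
corresponding points share image rows and the disparity of a scene point at
depth ``z`` is ``d = f_px * b / z`` pixels, where ``f_px`` is the focal length
expressed in pixels.

The design calculator answers the question a rig designer asks before building
anything: given a focal length, a baseline and the subpixel precision of the
matcher, how small a depth change can be resolved at working distance ``z``?
The answer is the depth resolution

    dz = z**2 * dd / (f * b)

with ``dd`` the disparity resolution in mm on the sensor (a fraction of the
physical pixel size).  ``dz`` grows with the square of the working distance and
shrinks inversely with baseline and focal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "DesignQuery",
    "depth_resolution",
    "disparity_resolution",
    "design_table",
    "project_point",
    "rectify_pair",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with square pixels and optional radial distortion.

    Parameters
    ----------
    focal_length_mm : float
        Effective focal length in mm.
    pixel_size_mm : float
        Physical side of a (square) sensor pixel in mm.
    principal_point : tuple of float
        (column, row) of the principal point, 0-based pixel coordinates.
    image_size : tuple of int
        (width, height) in pixels.
    radial_distortion : tuple of float
        Coefficients (k1, k2, ...) of the even radial polynomial
        ``r_d = r_u * (1 + k1 r_u^2 + k2 r_u^4 + ...)`` in normalized
        image coordinates.  Empty means no distortion.
    """

    focal_length_mm: float
    pixel_size_mm: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]
    radial_distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError(f"focal_length_mm must be > 0, got {self.focal_length_mm}")
        if self.pixel_size_mm <= 0:
            raise ValueError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        w, h = self.image_size
        cx, cy = self.principal_point
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(
                f"principal point {self.principal_point} outside image bounds {self.image_size}"
            )

    @property
    def focal_length_px(self) -> float:
        """Focal length in pixel units, f_mm / pixel_size_mm."""
        return self.focal_length_mm / self.pixel_size_mm


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("relative_rotation must be a 3x3 orthonormal matrix")
    return R


@dataclass(frozen=True)
class StereoRig:
    """Two cameras with a horizontal baseline; origin at the left optical center."""

    left: CameraIntrinsics
    right: CameraIntrinsics
    baseline_mm: float
    relative_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    rectified: bool = True

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise ValueError(f"baseline_mm must be > 0, got {self.baseline_mm}")
        object.__setattr__(self, "relative_rotation", _check_rotation(self.relative_rotation))
        if self.rectified and not np.allclose(self.relative_rotation, np.eye(3), atol=1e-10):
            raise ValueError("a rectified rig must have identity relative rotation")

    @property
    def focal_length_px(self) -> float:
        return self.left.focal_length_px


@dataclass(frozen=True)
class DesignQuery:
    """Inputs of the depth-resolution formula; all strictly positive, all mm."""

    depth_mm: float
    baseline_mm: float
    focal_length_mm: float
    disparity_resolution_mm: float

    def __post_init__(self) -> None:
        for name in ("depth_mm", "baseline_mm", "focal_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.disparity_resolution_mm < 0:
            raise ValueError("disparity_resolution_mm must be >= 0")


def depth_resolution(query: DesignQuery) -> float:
    """Smallest resolvable depth change dz = z^2 * dd / (f * b), in mm.

    With the reference design (z = 1524 mm, f = 3.38 mm, b = 152.4 mm,
    dd = 0.28 um) this evaluates to 1.26 mm.
    """
    q = query
    return q.depth_mm**2 * q.disparity_resolution_mm / (q.focal_length_mm * q.baseline_mm)


def disparity_resolution(pixel_size_mm: float, subpixel_fraction: float = 1 / 5) -> float:
    """Disparity resolution on the sensor: pixel size times the subpixel fraction.

    Matching with parabolic refinement localizes disparity to roughly a fifth
    of a pixel, the default fraction.
    """
    if pixel_size_mm <= 0:
        raise ValueError(f"pixel_size_mm must be > 0, got {pixel_size_mm}")
    if not 0 < subpixel_fraction <= 1:
        raise ValueError(f"subpixel_fraction must be in (0, 1], got {subpixel_fraction}")
    return pixel_size_mm * subpixel_fraction


def design_table(
    depth_range_mm: tuple[float, float],
    baseline_range_mm: tuple[float, float],
    steps: tuple[int, int],
    focal_length_mm: float,
    disparity_resolution_mm: float,
    require_dz_mm: float | None = None,
) -> pd.DataFrame:
    """Depth resolution over a Cartesian (depth x baseline) grid.

    Returns a DataFrame with columns ``depth_mm``, ``baseline_mm``, ``dz_mm``
    and, when ``require_dz_mm`` is given, a boolean ``meets_requirement``
    column that is True for a baseline iff dz <= require_dz_mm at *every*
    depth of the grid (the worst case is the far end of the range).
    """
    nz, nb = steps
    if nz < 1 or nb < 1:
        raise ValueError("steps must be >= 1 in both dimensions")
    z0, z1 = depth_range_mm
    b0, b1 = baseline_range_mm
    if z0 <= 0 or b0 <= 0 or z1 < z0 or b1 < b0:
        raise ValueError("ranges must be positive and non-empty")
    zs = np.linspace(z0, z1, nz)
    bs = np.linspace(b0, b1, nb)
    zz, bb = np.meshgrid(zs, bs, indexing="ij")
    dz = zz**2 * disparity_resolution_mm / (focal_length_mm * bb)
    table = pd.DataFrame(
        {"depth_mm": zz.ravel(), "baseline_mm": bb.ravel(), "dz_mm": dz.ravel()}
    )
    if require_dz_mm is not None:
        worst = table.groupby("baseline_mm")["dz_mm"].transform("max")
        table["meets_requirement"] = worst <= require_dz_mm
    return table


def project_point(point_mm: np.ndarray, rig: StereoRig) -> tuple[np.ndarray, np.ndarray]:
    """Project a 3-D point (mm, left-camera frame) into both rectified views.

    Returns ``((col_l, row_l), (col_r, row_r))``; rows are equal and the
    disparity ``col_l - col_r`` equals ``f_px * b / z``.
    """
    if not rig.rectified:
        raise ValueError("project_point requires a rectified rig")
    x, y, z = np.asarray(point_mm, dtype=float)
    if z <= 0:
        raise ValueError(f"point behind camera: z = {z}")
    f_px = rig.focal_length_px
    cxl, cyl = rig.left.principal_point
    cxr, cyr = rig.right.principal_point
    left = np.array([cxl + f_px * x / z, cyl + f_px * y / z])
    right = np.array([cxr + f_px * (x - rig.baseline_mm) / z, cyr + f_px * y / z])
    return left, right


# ---------------------------------------------------------------------------
# Rectification


def _distort_normalized(xu: np.ndarray, yu: np.ndarray, coeffs: tuple[float, ...]):
    """Apply the even radial polynomial to undistorted normalized coords."""
    if not coeffs:
        return xu, yu
    r2 = xu * xu + yu * yu
    scale = np.ones_like(r2)
    rpow = np.ones_like(r2)
    for k in coeffs:
        rpow = rpow * r2
        scale = scale + k * rpow
    return xu * scale, yu * scale


def _warp(img: np.ndarray, map_cols: np.ndarray, map_rows: np.ndarray) -> np.ndarray:
    """Bilinear inverse warp; out-of-bounds samples get the edge value."""
    return ndimage.map_coordinates(
        np.asarray(img, dtype=float), [map_rows, map_cols], order=1, mode="nearest"
    )


def _rectification_maps(cam: CameraIntrinsics, R_cam: np.ndarray, shape: tuple[int, int]):
    """Per-pixel sampling maps from the rectified grid into the raw image.

    ``R_cam`` maps left-frame (rectified) directions into the raw camera frame.
    Undistortion is folded in: rectified pixel -> ideal ray -> rotate into the
    raw camera -> apply the radial model -> raw pixel.
    """
    h, w = shape
    f_px = cam.focal_length_px
    cx, cy = cam.principal_point
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    # Ray direction of each rectified pixel, normalized coordinates.
    xn = (cols - cx) / f_px
    yn = (rows - cy) / f_px
    ones = np.ones_like(xn)
    rays = np.stack([xn, yn, ones], axis=0).reshape(3, -1)
    raw = R_cam @ rays
    xu = raw[0] / raw[2]
    yu = raw[1] / raw[2]
    xd, yd = _distort_normalized(xu, yu, cam.radial_distortion)
    map_cols = (cx + f_px * xd).reshape(h, w)
    map_rows = (cy + f_px * yd).reshape(h, w)
    return map_cols, map_rows


def rectify_pair(
    left_img: np.ndarray, right_img: np.ndarray, rig: StereoRig
) -> tuple[np.ndarray, np.ndarray, StereoRig]:
    """Row-align a raw stereo pair and remove radial distortion.

    The left camera defines the rectified frame (its rotation is the
    identity); the right image is resampled through the homography induced by
    the rig's relative rotation.  Both images are undistorted with their
    camera's radial model.  Returns the rectified pair and a rig flagged
    ``rectified`` with the rotation reset to identity.
    """
    left_img = np.asarray(left_img, dtype=float)
    right_img = np.asarray(right_img, dtype=float)
    for img, cam, name in ((left_img, rig.left, "left"), (right_img, rig.right, "right")):
        w, h = cam.image_size
        if img.shape[:2] != (h, w):
            raise ValueError(
                f"{name} image shape {img.shape[:2]} does not match declared size {(h, w)}"
            )
    if rig.rectified and not rig.left.radial_distortion and not rig.right.radial_distortion:
        return left_img, right_img, rig

    shape_l = left_img.shape[:2]
    shape_r = right_img.shape[:2]
    mc_l, mr_l = _rectification_maps(rig.left, np.eye(3), shape_l)
    mc_r, mr_r = _rectification_maps(rig.right, rig.relative_rotation, shape_r)
    rect_left = _warp(left_img, mc_l, mr_l)
    rect_right = _warp(right_img, mc_r, mr_r)
    new_rig = replace(
        rig,
        left=replace(rig.left, radial_distortion=()),
        right=replace(rig.right, radial_distortion=()),
        relative_rotation=np.eye(3),
        rectified=True,
    )
    return rect_left, rect_right, new_rig
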
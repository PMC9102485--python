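"""Voxel-bar volume integration referenced to a fitted base plane.

The tray (or plate) surface is the zero-height reference.  Every
reconstructed food-surface point carries a voxel bar: a column of footprint
``A_voxel`` (mm^2) reaching from the base plane up to the point, of height
``h_vbar`` = the point's distance above the plane, clamped at zero (the food
is assumed to have a flat bottom on the tray).  The object volume is

    V = sum_i A_voxel * h_vbar_i   (mm^3, reported in mL)

Two footprint conventions are supported.  ``fixed`` mode squares a configured
lateral resolution (the deployed device assumes 0.55 mm/px at all depths);
``metric`` mode derives the footprint from the rig geometry as
``(z / f_px)^2`` — the physical size of one pixel's back-projection at depth
``z`` — which is the physically consistent choice and the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import PointCloud
from .rig import StereoRig

__all__ = [
    "BasePlane",
    "VolumeEstimate",
    "fit_base_plane",
    "voxel_heights",
    "integrate_volume",
    "pixel_footprint",
    "auto_food_mask",
]

DEFAULT_FIXED_RESOLUTION_MM = 0.55


@dataclass(frozen=True)
class BasePlane:
    """Unit-normal plane ``n . p = offset`` with fit diagnostics."""

    normal: tuple[float, float, float]
    offset_mm: float
    residual_rms_mm: float
    n_inliers: int

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
            raise ValueError("plane normal must be unit length")

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        """Height of points above the plane, positive toward the camera."""
        n = np.asarray(self.normal)
        return self.offset_mm - points @ n


@dataclass(frozen=True)
class VolumeEstimate:
    """Summed voxel-bar volume with its footprint and height summary."""

    volume_ml: float
    n_bars: int
    A_voxel_mm2: float
    mode: str
    height_min_mm: float
    height_max_mm: float
    height_mean_mm: float


def _plane_from_lstsq(pts: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Total-least-squares plane through points; returns (normal, offset, residuals)."""
    centroid = pts.mean(axis=0)
    q = pts - centroid
    # smallest singular vector of the centered cloud is the plane normal
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    offset = float(normal @ centroid)
    residuals = q @ normal
    return normal, offset, residuals


def fit_base_plane(
    cloud: PointCloud,
    tray_mask: np.ndarray,
    robust: bool = True,
    inlier_threshold_mm: float | None = None,
    seed: int = 0,
    n_iterations: int = 50,
) -> BasePlane:
    """Fit the tray plane to the masked points.

    Plain mode is a total-least-squares fit.  Robust mode runs a small
    consensus search: random minimal triples propose planes, the plane with
    the most inliers (within ``inlier_threshold_mm``) wins, and the final
    plane is re-fit by least squares on its inliers.  The default threshold
    is 2 mm, roughly twice the depth resolution at the design working
    distance.
    """
    tray_mask = np.asarray(tray_mask, dtype=bool)
    if tray_mask.shape != cloud.points.shape[:2]:
        raise ValueError("tray mask shape does not match the cloud grid")
    pts = cloud.points[tray_mask & cloud.valid]
    if len(pts) < 3:
        raise ValueError(f"plane fit needs >= 3 points, got {len(pts)}")
    if inlier_threshold_mm is None:
        inlier_threshold_mm = 2.0

    if not robust:
        normal, offset, res = _plane_from_lstsq(pts)
        _check_degenerate(res, pts)
        rms = float(np.sqrt(np.mean(res**2)))
        return BasePlane(tuple(normal), offset, rms, len(pts))

    rng = np.random.default_rng(seed)
    best_inliers = None
    best_count = -1
    n = len(pts)
    for _ in range(n_iterations):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        nvec = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nvec)
        if norm < 1e-9:
            continue
        nvec = nvec / norm
        dist = np.abs((pts - p0) @ nvec)
        inl = dist <= inlier_threshold_mm
        count = int(inl.sum())
        if count > best_count:
            best_count = count
            best_inliers = inl
    if best_inliers is None or best_count < 3:
        raise ValueError("consensus plane fit failed: all sampled triples degenerate")
    normal, offset, res = _plane_from_lstsq(pts[best_inliers])
    _check_degenerate(res, pts[best_inliers])
    rms = float(np.sqrt(np.mean(res**2)))
    return BasePlane(tuple(normal), offset, rms, best_count)


def _check_degenerate(residuals: np.ndarray, pts: np.ndarray) -> None:
    # collinear points leave the in-plane spread rank-deficient
    spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if spread[1] < 1e-9:
        raise ValueError("degenerate plane fit: tray points are collinear")


def voxel_heights(
    cloud: PointCloud, plane: BasePlane, food_mask: np.ndarray
) -> np.ndarray:
    """Per-food-pixel bar height: point-to-plane distance clamped at zero.

    Returns a flat array over the valid masked pixels (NaN points excluded).
    """
    food_mask = np.asarray(food_mask, dtype=bool)
    if food_mask.shape != cloud.points.shape[:2]:
        raise ValueError("food mask shape does not match the cloud grid")
    if not food_mask.any():
        raise ValueError("empty food mask")
    pts = cloud.points[food_mask & cloud.valid]
    if len(pts) == 0:
        raise ValueError("no valid reconstructed points inside the food mask")
    return np.maximum(plane.signed_height(pts), 0.0)


def integrate_volume(
    heights_mm: np.ndarray, A_voxel_mm2: float, mode: str = "metric"
) -> VolumeEstimate:
    """Sum the voxel bars: V = sum(A_voxel * h) / 1000 mL, exact arithmetic."""
    heights_mm = np.asarray(heights_mm, dtype=float)
    if (heights_mm < 0).any():
        raise ValueError("voxel-bar heights must be non-negative")
    if A_voxel_mm2 <= 0:
        raise ValueError("A_voxel_mm2 must be > 0")
    volume_ml = float(heights_mm.sum() * A_voxel_mm2 / 1000.0)
    return VolumeEstimate(
        volume_ml=volume_ml,
        n_bars=int(heights_mm.size),
        A_voxel_mm2=float(A_voxel_mm2),
        mode=mode,
        height_min_mm=float(heights_mm.min()) if heights_mm.size else 0.0,
        height_max_mm=float(heights_mm.max()) if heights_mm.size else 0.0,
        height_mean_mm=float(heights_mm.mean()) if heights_mm.size else 0.0,
    )


def pixel_footprint(
    rig: StereoRig | None,
    depth_mm: float | None = None,
    mode: str = "metric",
    fixed_resolution_mm: float = DEFAULT_FIXED_RESOLUTION_MM,
) -> float:
    """Voxel footprint A_voxel in mm^2.

    ``fixed`` squares the configured lateral resolution regardless of depth
    (0.55 mm default, the deployed-device assumption).  ``metric`` squares the
    physical back-projection of one pixel, ``depth / f_px``.
    """
    if mode == "fixed":
        if fixed_resolution_mm <= 0:
            raise ValueError("fixed_resolution_mm must be > 0")
        return fixed_resolution_mm**2
    if mode == "metric":
        if rig is None:
            raise ValueError("metric mode needs the rig geometry")
        if depth_mm is None or depth_mm <= 0:
            raise ValueError("metric mode needs a positive depth")
        return (depth_mm / rig.focal_length_px) ** 2
    raise ValueError(f"unknown footprint mode {mode!r}; expected 'fixed' or 'metric'")


def auto_food_mask(
    cloud: PointCloud, plane: BasePlane, factor: float = 3.0
) -> np.ndarray:
    """Convenience foreground mask: points more than ``factor`` x the plane
    residual RMS (at least 1 mm) above the base plane.  A stand-in for manual
    segmentation, not a substitute for it.
    """
    thresh = max(factor * plane.residual_rms_mm, 1.0)
    heights = plane.signed_height(cloud.points)
    return np.nan_to_num(heights, nan=-np.inf) > thresh
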
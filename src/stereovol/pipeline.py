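"""End-to-end pipeline: rectify -> match -> refine -> triangulate -> volume.

`estimate_volume_from_pair` is the in-memory pipeline used by tests and the
simulator studies; `run_pipeline` is the on-disk variant behind the CLI,
writing the intermediate disparity TIFF, the PLY cloud, and a JSON result
with a provenance record (configuration, seed, package version).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as svio
from .refine import RefineParams, gaussian_fill, median_smooth
from .reconstruct import PointCloud, triangulate_map
from .rig import StereoRig, rectify_pair
from .sgm import SGMParams, compute_disparity
from .simulate import SceneSpec, render_stereo_pair
from .volume import (
    BasePlane,
    VolumeEstimate,
    fit_base_plane,
    integrate_volume,
    pixel_footprint,
    voxel_heights,
)

__all__ = ["PipelineConfig", "PipelineResult", "default_sgm_params",
           "estimate_volume_from_pair", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; all randomness flows from ``seed``."""

    rig_path: str | None = None
    scene_path: str | None = None
    left_path: str | None = None
    right_path: str | None = None
    tray_mask_path: str | None = None
    food_mask_path: str | None = None
    sgm: SGMParams | None = None
    refine: RefineParams = field(default_factory=RefineParams)
    volume_mode: str = "metric"
    fixed_resolution_mm: float = 0.55
    seed: int = 0
    out_dir: str = "."


@dataclass
class PipelineResult:
    volume: VolumeEstimate
    plane: BasePlane
    disparity: np.ndarray
    cloud: PointCloud


def default_sgm_params(
    rig: StereoRig,
    tray_depth_mm: float = 1524.0,
    band_below_mm: float = 300.0,
    band_above_mm: float = 50.0,
) -> SGMParams:
    """Search range from the rig and a depth band around the tray plane.

    Objects sit on the tray, so plausible surfaces live in
    ``[tray - band_below, tray + band_above]``; the disparity bounds are that
    band pushed through d = f_px b / z.
    """
    fb = rig.focal_length_px * rig.baseline_mm
    d_min = int(np.floor(fb / (tray_depth_mm + band_above_mm)))
    d_max = int(np.ceil(fb / max(tray_depth_mm - band_below_mm, 1.0)))
    return SGMParams(d_min=max(d_min, 0), d_max=d_max)


def estimate_volume_from_pair(
    left: np.ndarray,
    right: np.ndarray,
    rig: StereoRig,
    tray_mask: np.ndarray,
    food_mask: np.ndarray,
    sgm_params: SGMParams | None = None,
    refine_params: RefineParams | None = None,
    volume_mode: str = "metric",
    fixed_resolution_mm: float = 0.55,
    seed: int = 0,
) -> PipelineResult:
    """Rectified pair + masks -> voxel-bar volume estimate.

    The base plane is fit robustly to the tray-mask points; the metric voxel
    footprint is evaluated at the mean depth of the food-surface points, so a
    flat top's pixel count times footprint reproduces its physical area.
    """
    if sgm_params is None:
        sgm_params = default_sgm_params(rig)
    refine_params = refine_params or RefineParams()

    disp = compute_disparity(left, right, sgm_params)
    disp = gaussian_fill(disp, refine_params)
    disp = median_smooth(disp, refine_params)
    cloud = triangulate_map(disp, rig)

    plane = fit_base_plane(cloud, tray_mask, robust=True, seed=seed)
    heights = voxel_heights(cloud, plane, food_mask)

    if volume_mode == "metric":
        food_pts = cloud.points[np.asarray(food_mask, bool) & cloud.valid]
        depth = float(np.nanmean(food_pts[:, 2]))
        A = pixel_footprint(rig, depth, mode="metric")
    else:
        A = pixel_footprint(None, mode="fixed", fixed_resolution_mm=fixed_resolution_mm)
    est = integrate_volume(heights, A, mode=volume_mode)
    return PipelineResult(volume=est, plane=plane, disparity=disp.disparity, cloud=cloud)


def run_pipeline(config: PipelineConfig) -> dict:
    """Disk-to-disk run; returns the JSON-serializable result record.

    Inputs are either a simulator scene (``scene_path``) or an image pair
    with masks; a rig file is required for real pairs and optional for
    simulated ones (the default simulation rig is used otherwise).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.rig_path is not None:
        rig = svio.load_rig(_must_exist(config.rig_path, "rig file"))
    elif config.scene_path is not None:
        from .simulate import simulation_rig

        rig = simulation_rig()
    else:
        raise ValueError("configuration error: need rig_path (or scene_path)")

    if config.scene_path is not None:
        scene = svio.load_scene(_must_exist(config.scene_path, "scene file"))
        if scene.seed == 0 and config.seed:
            from dataclasses import replace

            scene = replace(scene, seed=config.seed)
        left, right, gt = render_stereo_pair(scene, rig)
        tray_mask, food_mask = gt.tray_mask, gt.roi_mask
        gt_volume = gt.volume_ml
    else:
        left = svio.read_image(_must_exist(config.left_path, "left image"))
        right = svio.read_image(_must_exist(config.right_path, "right image"))
        if not rig.rectified:
            left, right, rig = rectify_pair(left, right, rig)
        tray_mask = svio.read_image(_must_exist(config.tray_mask_path, "tray mask")) > 127
        food_mask = svio.read_image(_must_exist(config.food_mask_path, "food mask")) > 127
        gt_volume = None

    sgm_params = config.sgm or default_sgm_params(rig)
    result = estimate_volume_from_pair(
        left, right, rig, tray_mask, food_mask,
        sgm_params=sgm_params, refine_params=config.refine,
        volume_mode=config.volume_mode,
        fixed_resolution_mm=config.fixed_resolution_mm, seed=config.seed,
    )

    svio.write_disparity(out / "disparity.tiff", result.disparity)
    svio.write_ply(out / "cloud.ply", result.cloud.points)

    from . import __version__

    record = {
        "volume_ml": result.volume.volume_ml,
        "n_bars": result.volume.n_bars,
        "A_voxel_mm2": result.volume.A_voxel_mm2,
        "mode": result.volume.mode,
        "plane": {
            "normal": list(result.plane.normal),
            "offset_mm": result.plane.offset_mm,
            "residual_rms_mm": result.plane.residual_rms_mm,
            "n_inliers": result.plane.n_inliers,
        },
        "ground_truth_ml": gt_volume,
        "provenance": {
            "seed": config.seed,
            "sgm": asdict(sgm_params),
            "refine": asdict(config.refine),
            "volume_mode": config.volume_mode,
            "version": __version__,
            "python": platform.python_version(),
        },
    }
    with open(out / "result.json", "w") as f:
        json.dump(record, f, indent=2, sort_keys=True)
    return record


def _must_exist(path: str | None, what: str) -> str:
    if path is None:
        raise ValueError(f"configuration error: {what} not given")
    if not Path(path).exists():
        raise FileNotFoundError(f"configuration error: {what} not found at {path!r}")
    return path
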
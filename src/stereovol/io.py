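"""Readers and writers for the pipeline's on-disk formats.

Images: 8-bit PNG in, 32-bit float TIFF for disparity maps (NaN marks
invalid pixels and survives the round trip).  Point clouds: binary
little-endian PLY via trimesh, NaN points dropped on write.  Rig and scene
descriptions: YAML.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import trimesh
import yaml

from .rig import CameraIntrinsics, StereoRig
from .simulate import SceneSpec, ShapePrimitive

__all__ = [
    "read_image",
    "write_image",
    "read_disparity",
    "write_disparity",
    "write_ply",
    "read_ply",
    "load_rig",
    "save_rig",
    "load_scene",
]


def read_image(path) -> np.ndarray:
    """Read an image as float grayscale (RGB collapsed by the luminance mean)."""
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img


def write_image(path, img: np.ndarray) -> None:
    """Write a float image clipped to 0-255 as 8-bit PNG."""
    iio.imwrite(path, np.clip(img, 0, 255).astype(np.uint8))


def write_disparity(path, disparity: np.ndarray) -> None:
    """Write a disparity map as 32-bit float TIFF; invalid pixels are NaN."""
    tifffile.imwrite(path, np.asarray(disparity, dtype=np.float32))


def read_disparity(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_ply(path, points: np.ndarray) -> None:
    """Write an (N, 3) or organized (H, W, 3) cloud as binary PLY, NaN dropped."""
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) == 0:
        raise ValueError("no finite points to write")
    trimesh.PointCloud(pts).export(str(path), file_type="ply")


def read_ply(path) -> np.ndarray:
    cloud = trimesh.load(str(path), process=False)
    return np.asarray(cloud.vertices, dtype=np.float32)


def load_rig(path) -> StereoRig:
    """Load a stereo rig from YAML/JSON.

    Keys: focal_length_mm, pixel_size_mm, baseline_mm, principal_point,
    image_size, radial_distortion (optional), relative_rotation (optional),
    rectified (optional, default true when no rotation given).  Per-camera
    overrides may be nested under ``left:`` / ``right:``.
    """
    with open(path) as f:
        spec = yaml.safe_load(f)
    return rig_from_dict(spec)


def rig_from_dict(spec: dict) -> StereoRig:
    def cam(side: str) -> CameraIntrinsics:
        merged = {**spec, **spec.get(side, {})}
        try:
            return CameraIntrinsics(
                focal_length_mm=float(merged["focal_length_mm"]),
                pixel_size_mm=float(merged["pixel_size_mm"]),
                principal_point=tuple(merged["principal_point"]),
                image_size=tuple(merged["image_size"]),
                radial_distortion=tuple(merged.get("radial_distortion", ()) or ()),
            )
        except KeyError as e:
            raise ValueError(f"rig file missing key {e.args[0]!r}") from None

    rotation = np.asarray(spec.get("relative_rotation", np.eye(3)), dtype=float)
    identity = np.allclose(rotation, np.eye(3))
    rectified = bool(spec.get("rectified", identity))
    if "baseline_mm" not in spec:
        raise ValueError("rig file missing key 'baseline_mm'")
    return StereoRig(
        left=cam("left"),
        right=cam("right"),
        baseline_mm=float(spec["baseline_mm"]),
        relative_rotation=rotation,
        rectified=rectified,
    )


def save_rig(path, rig: StereoRig) -> None:
    spec = {
        "focal_length_mm": rig.left.focal_length_mm,
        "pixel_size_mm": rig.left.pixel_size_mm,
        "principal_point": list(rig.left.principal_point),
        "image_size": list(rig.left.image_size),
        "radial_distortion": list(rig.left.radial_distortion),
        "baseline_mm": rig.baseline_mm,
        "relative_rotation": np.asarray(rig.relative_rotation).tolist(),
        "rectified": rig.rectified,
        "right": {
            "principal_point": list(rig.right.principal_point),
            "radial_distortion": list(rig.right.radial_distortion),
        },
    }
    with open(path, "w") as f:
        yaml.safe_dump(spec, f, sort_keys=False)


def load_scene(path) -> SceneSpec:
    """Load a simulator scene from YAML.

    Top-level keys mirror SceneSpec; ``primitives`` is a list of mappings
    with ``kind``, ``position`` and the kind-specific parameters inline.
    """
    with open(path) as f:
        spec = yaml.safe_load(f)
    prims = []
    for p in spec.get("primitives", []):
        p = dict(p)
        kind = p.pop("kind")
        position = tuple(p.pop("position", (0.0, 0.0)))
        prims.append(ShapePrimitive(kind=kind, parameters=p, position=position))
    fields = {
        k: spec[k]
        for k in (
            "tray_depth_mm", "dot_density", "dot_sigma_px",
            "background_reflectance", "noise_sigma", "specular_spots", "seed",
        )
        if k in spec
    }
    return SceneSpec(primitives=tuple(prims), **fields)
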
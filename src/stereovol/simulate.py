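"""Synthetic structured-light stereo scenes with analytic ground truth.

The simulator emulates the capture geometry of an overhead structured-light
stereo rig: parametric shapes sit on a flat tray plane fronto-parallel to a
rectified stereo pair, an infrared-style random dot pattern supplies the
artificial texture that makes otherwise featureless surfaces matchable, and
every scene comes with exact ground truth — the heightfield above the tray,
the left-referenced disparity map, occlusion and footprint masks, and the
closed-form volume of each shape.

Rendering is correspondence-exact rather than photorealistic: the left image
is the dot-pattern texture itself, and the right image is synthesized by
sampling that texture at the ground-truth corresponding left coordinate of
each right pixel (bilinear).  Surface depths along each pixel ray are found by
marching the ray through the solid ``tray_z >= z >= tray_z - h(x, y)`` and
bisecting the entry point, which handles vertical side walls (slabs,
cylinders) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rig import CameraIntrinsics, StereoRig

__all__ = [
    "ShapePrimitive",
    "SceneSpec",
    "GroundTruth",
    "analytic_volume",
    "generate_dot_pattern",
    "render_stereo_pair",
    "simulation_rig",
]

_KINDS = ("slab", "box", "hemisphere", "cylinder", "gaussian-bump", "random-heightfield")


@dataclass(frozen=True)
class ShapePrimitive:
    """A non-negative heightfield of finite support placed on the tray.

    kind-specific ``parameters`` (all mm):
      slab / box          size_x, size_y, height
      hemisphere          radius
      cylinder            radius, height
      gaussian-bump       amplitude, sigma (support truncated at 5 sigma)
      random-heightfield  size_x, size_y, amplitude, correlation_mm, seed
    """

    kind: str
    parameters: dict
    position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}; expected one of {_KINDS}")

    # -- geometry ----------------------------------------------------------

    def max_height(self) -> float:
        p = self.parameters
        if self.kind in ("slab", "box"):
            return float(p["height"])
        if self.kind == "hemisphere":
            return float(p["radius"])
        if self.kind == "cylinder":
            return float(p["height"])
        if self.kind == "gaussian-bump":
            return float(p["amplitude"])
        return float(p["amplitude"])

    def support_halfwidth(self) -> tuple[float, float]:
        """Half-extent (mm) of the support rectangle around ``position``."""
        p = self.parameters
        if self.kind in ("slab", "box"):
            return p["size_x"] / 2, p["size_y"] / 2
        if self.kind in ("hemisphere", "cylinder"):
            return p["radius"], p["radius"]
        if self.kind == "gaussian-bump":
            r = 5.0 * p["sigma"]
            return r, r
        return p["size_x"] / 2, p["size_y"] / 2

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Height (mm) above the tray at world coordinates (x, y) mm."""
        p = self.parameters
        x0, y0 = self.position
        dx = np.asarray(x, dtype=float) - x0
        dy = np.asarray(y, dtype=float) - y0
        if self.kind in ("slab", "box"):
            inside = (np.abs(dx) <= p["size_x"] / 2) & (np.abs(dy) <= p["size_y"] / 2)
            return np.where(inside, p["height"], 0.0)
        if self.kind == "hemisphere":
            r2 = dx * dx + dy * dy
            return np.sqrt(np.maximum(p["radius"] ** 2 - r2, 0.0))
        if self.kind == "cylinder":
            inside = dx * dx + dy * dy <= p["radius"] ** 2
            return np.where(inside, p["height"], 0.0)
        if self.kind == "gaussian-bump":
            r2 = dx * dx + dy * dy
            h = p["amplitude"] * np.exp(-r2 / (2 * p["sigma"] ** 2))
            return np.where(r2 <= (5 * p["sigma"]) ** 2, h, 0.0)
        return self._random_height(dx, dy)

    def _random_height(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Smooth seeded random field, windowed to zero at the support edge."""
        p = self.parameters
        sx, sy = p["size_x"], p["size_y"]
        grid = self._random_grid()
        step = p["correlation_mm"] / 4
        gx = np.clip((dx + sx / 2) / step, 0, grid.shape[1] - 1)
        gy = np.clip((dy + sy / 2) / step, 0, grid.shape[0] - 1)
        vals = ndimage.map_coordinates(grid, [np.atleast_1d(gy).ravel(), np.atleast_1d(gx).ravel()],
                                       order=1, mode="nearest")
        vals = vals.reshape(np.broadcast(dx, dy).shape)
        wx = np.clip(np.cos(np.pi * dx / sx), 0, None)
        wy = np.clip(np.cos(np.pi * dy / sy), 0, None)
        inside = (np.abs(dx) <= sx / 2) & (np.abs(dy) <= sy / 2)
        return np.where(inside, vals * wx * wy, 0.0)

    def _random_grid(self) -> np.ndarray:
        p = self.parameters
        rng = np.random.default_rng(p.get("seed", 0))
        step = p["correlation_mm"] / 4
        nx = int(np.ceil(p["size_x"] / step)) + 1
        ny = int(np.ceil(p["size_y"] / step)) + 1
        raw = rng.standard_normal((ny, nx))
        smooth = ndimage.gaussian_filter(raw, sigma=4.0, mode="nearest")
        smooth -= smooth.min()
        if smooth.max() > 0:
            smooth /= smooth.max()
        return smooth * p["amplitude"]


def analytic_volume(shape: ShapePrimitive) -> float:
    """Ground-truth volume in mL (closed form; Riemann sum for random fields).

    slab/box: w*l*h; hemisphere: (2/3) pi R^3; cylinder: pi R^2 h;
    gaussian bump: 2 pi A sigma^2 (minus the truncated tail beyond 5 sigma,
    which is < 1e-9 of the total and ignored).
    """
    p = shape.parameters
    if shape.kind in ("slab", "box"):
        mm3 = p["size_x"] * p["size_y"] * p["height"]
    elif shape.kind == "hemisphere":
        mm3 = (2.0 / 3.0) * np.pi * p["radius"] ** 3
    elif shape.kind == "cylinder":
        mm3 = np.pi * p["radius"] ** 2 * p["height"]
    elif shape.kind == "gaussian-bump":
        mm3 = 2.0 * np.pi * p["amplitude"] * p["sigma"] ** 2
    else:
        mm3 = _riemann_volume(shape, grid_mm=0.2)
    return mm3 / 1000.0


def _riemann_volume(shape: ShapePrimitive, grid_mm: float = 0.2) -> float:
    hx, hy = shape.support_halfwidth()
    x0, y0 = shape.position
    xs = np.arange(x0 - hx, x0 + hx + grid_mm, grid_mm)
    ys = np.arange(y0 - hy, y0 + hy + grid_mm, grid_mm)
    xx, yy = np.meshgrid(xs, ys)
    return float(shape.height(xx, yy).sum() * grid_mm * grid_mm)


@dataclass(frozen=True)
class SceneSpec:
    """A tray plane with primitives, texture and noise settings.

    ``tray_depth_mm`` is the distance from the rig to the tray plane (default
    1524 mm, the working distance the rig was designed for).  ``dot_density``
    is expected dots per 1000 px^2 of image.  ``noise_sigma`` is the standard
    deviation of additive Gaussian intensity noise on a 0-255 scale, drawn
    independently per eye (the two eyes of the emulated device do not expose
    at the same instant).  ``specular_spots`` injects saturated blobs at
    independent positions in the two views, reproducing the disparity noise
    that bright reflections on the table cause; off by default.
    """

    primitives: tuple[ShapePrimitive, ...]
    tray_depth_mm: float = 1524.0
    dot_density: float = 50.0
    dot_sigma_px: float = 1.0
    background_reflectance: float = 60.0
    noise_sigma: float = 0.0
    specular_spots: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tray_depth_mm <= 0:
            raise ValueError("tray_depth_mm must be > 0")
        object.__setattr__(self, "primitives", tuple(self.primitives))

    def heightfield(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        h = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for prim in self.primitives:
            h = np.maximum(h, prim.height(x, y))
        return h

    def analytic_volume_ml(self) -> float:
        return sum(analytic_volume(p) for p in self.primitives)


@dataclass
class GroundTruth:
    """Exact per-pixel truth on the left-image grid."""

    heightfield: np.ndarray          # mm above the tray at each left pixel's surface point
    volume_ml: float                 # analytic volume of the primitives
    disparity_map: np.ndarray        # ideal left-referenced disparity, px
    roi_mask: np.ndarray             # bool, primitive footprint (left view)
    occlusion_mask: np.ndarray       # bool, left pixels not visible from the right camera
    tray_mask: np.ndarray = field(default=None)  # bool, tray pixels clear of the food margin
    depth_map: np.ndarray = field(default=None)  # mm, surface depth per left pixel


def generate_dot_pattern(
    width: int,
    height: int,
    density: float,
    dot_sigma_px: float = 1.0,
    seed: int = 0,
    background: float = 60.0,
    amplitude: float = 160.0,
) -> np.ndarray:
    """Random dot texture: Poisson-count dots with a Gaussian profile.

    ``density`` is the expected number of dots per 1000 px^2; the realized
    count is Poisson.  Intensities are on a 0-255 scale, clipped.
    """
    if width <= 0 or height <= 0:
        raise ValueError("pattern area must be positive")
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), float(background))
    n = rng.poisson(density * width * height / 1000.0)
    if n == 0:
        return img
    xs = rng.uniform(0, width, n)
    ys = rng.uniform(0, height, n)
    r = max(int(np.ceil(3 * dot_sigma_px)), 1)
    win = np.arange(-r, r + 1)
    wy, wx = np.meshgrid(win, win, indexing="ij")
    for x, y in zip(xs, ys):
        ci, ri = int(round(x)), int(round(y))
        fx, fy = x - ci, y - ri
        blob = amplitude * np.exp(-(((wx - fx) ** 2 + (wy - fy) ** 2) / (2 * dot_sigma_px**2)))
        c0, c1 = max(ci - r, 0), min(ci + r + 1, width)
        r0, r1 = max(ri - r, 0), min(ri + r + 1, height)
        img[r0:r1, c0:c1] += blob[r0 - ri + r : r1 - ri + r, c0 - ci + r : c1 - ci + r]
    return np.clip(img, 0.0, 255.0)


def simulation_rig(
    image_size: tuple[int, int] = (480, 360),
    focal_length_mm: float = 8.0,
    pixel_size_mm: float = 0.005,
    baseline_mm: float = 152.4,
) -> StereoRig:
    """Default rectified rig for simulation.

    Keeps the reference baseline (152.4 mm) and working distance class of the
    target device but uses f_px = 1600 so the tray at 1524 mm maps to a
    disparity of exactly 160 px, leaving ~2/3 of a 480-px frame of stereo
    overlap (the real sensor's f_px ~ 2414 would leave almost none at this
    frame size).
    """
    w, h = image_size
    cam = CameraIntrinsics(
        focal_length_mm=focal_length_mm,
        pixel_size_mm=pixel_size_mm,
        principal_point=((w - 1) / 2.0, (h - 1) / 2.0),
        image_size=(w, h),
    )
    return StereoRig(left=cam, right=cam, baseline_mm=baseline_mm, rectified=True)


def _surface_depth(
    scene: SceneSpec, rig: StereoRig, camera_x_mm: float, shape: tuple[int, int],
    principal: tuple[float, float],
) -> np.ndarray:
    """Depth (mm) of the first surface hit along each pixel ray of one camera.

    March each ray front-to-back through the solid ``z >= tray - h(x, y)``
    with 0.5 mm steps, then bisect the entry interval to ~1e-3 mm.
    """
    h_px, w_px = shape
    f_px = rig.focal_length_px
    cx, cy = principal
    cols, rows = np.meshgrid(np.arange(w_px, dtype=float), np.arange(h_px, dtype=float))
    sx = (cols - cx) / f_px  # dx/dz of the ray
    sy = (rows - cy) / f_px

    tray = scene.tray_depth_mm
    h_max = max((p.max_height() for p in scene.primitives), default=0.0)

    def inside(z):
        x = camera_x_mm + sx * z
        y = sy * z
        return z >= tray - scene.heightfield(x, y)

    if h_max <= 0:
        return np.full(shape, tray)
    step = 0.5
    z_lo = np.full(shape, tray - h_max - step)
    hit = np.zeros(shape, dtype=bool)
    z_hit = np.full(shape, tray)
    z = tray - h_max
    while z < tray + step / 2:
        zc = min(z, tray)
        new = inside(zc) & ~hit
        z_hit[new] = zc
        z_lo[~hit & ~new] = zc
        hit |= new
        z += step
    # un-hit rays end on the tray exactly
    z_hit[~hit] = tray
    z_lo[~hit] = tray
    # bisection refine between last-outside z_lo and first-inside z_hit
    for _ in range(14):
        mid = 0.5 * (z_lo + z_hit)
        ins = inside(mid)
        z_hit = np.where(ins, mid, z_hit)
        z_lo = np.where(ins, z_lo, mid)
    return z_hit


def render_stereo_pair(
    scene: SceneSpec, rig: StereoRig, pattern_on: bool = True
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a rectified stereo pair and its exact ground truth.

    The left image is the texture itself; each right pixel samples the left
    texture at its ground-truth corresponding column (bilinear), so with zero
    noise corresponding points have identical intensity by construction.
    Additive Gaussian noise is drawn independently per eye.
    """
    if not rig.rectified:
        raise ValueError("render_stereo_pair requires a rectified rig")
    w, h = rig.left.image_size
    f_px = rig.focal_length_px
    b = rig.baseline_mm

    _check_in_view(scene, rig)

    z_left = _surface_depth(scene, rig, 0.0, (h, w), rig.left.principal_point)
    z_right = _surface_depth(scene, rig, b, (h, w), rig.right.principal_point)
    d_left = f_px * b / z_left
    d_right = f_px * b / z_right

    cxl, cyl = rig.left.principal_point
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x_surf = (cols - cxl) * z_left / f_px
    y_surf = (rows - cyl) * z_left / f_px
    height = scene.heightfield(x_surf, y_surf)
    roi = height > 1e-9

    # occlusion: left pixel p maps to right column c - d_L; visible iff the
    # right camera's disparity there agrees.
    c_right = cols - d_left
    d_right_at = ndimage.map_coordinates(d_right, [rows, c_right], order=1, mode="nearest")
    occl = (np.abs(d_right_at - d_left) > 0.7) | (c_right < 0) | (c_right > w - 1)

    rng = np.random.default_rng(scene.seed)
    if pattern_on:
        texture = generate_dot_pattern(
            w, h, scene.dot_density, scene.dot_sigma_px,
            seed=int(rng.integers(2**31)), background=scene.background_reflectance,
        )
    else:
        texture = np.full((h, w), float(scene.background_reflectance))

    left = texture.copy()
    right = ndimage.map_coordinates(texture, [rows, cols + d_right], order=1, mode="nearest")

    if scene.specular_spots:
        for img in (left, right):
            _add_specular(img, scene.specular_spots, rng)
    if scene.noise_sigma > 0:
        left = left + rng.normal(0, scene.noise_sigma, left.shape)
        right = right + rng.normal(0, scene.noise_sigma, right.shape)
    left = np.clip(left, 0, 255)
    right = np.clip(right, 0, 255)

    tray_mask = ~ndimage.binary_dilation(roi, iterations=6) & ~occl
    gt = GroundTruth(
        heightfield=height,
        volume_ml=scene.analytic_volume_ml(),
        disparity_map=d_left,
        roi_mask=roi,
        occlusion_mask=occl,
        tray_mask=tray_mask,
        depth_map=z_left,
    )
    return left, right, gt


def _add_specular(img: np.ndarray, n: int, rng: np.random.Generator) -> None:
    h, w = img.shape
    for _ in range(n):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        sig = rng.uniform(2, 5)
        cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        img += 255.0 * np.exp(-(((cols - x) ** 2 + (rows - y) ** 2) / (2 * sig**2)))
    np.clip(img, 0, 255, out=img)


def _check_in_view(scene: SceneSpec, rig: StereoRig) -> None:
    """Every primitive's support, at its top depth, must project inside both views."""
    w, h = rig.left.image_size
    f_px = rig.focal_length_px
    for prim in scene.primitives:
        hx, hy = prim.support_halfwidth()
        x0, y0 = prim.position
        z_top = scene.tray_depth_mm - prim.max_height()
        for cam_x, (cx, cy) in ((0.0, rig.left.principal_point), (rig.baseline_mm, rig.right.principal_point)):
            for ex, ey in ((x0 - hx, y0 - hy), (x0 + hx, y0 + hy)):
                c = cx + f_px * (ex - cam_x) / z_top
                r = cy + f_px * ey / z_top
                if not (0 <= c <= w - 1 and 0 <= r <= h - 1):
                    raise ValueError(
                        f"primitive {prim.kind} at {prim.position} projects outside the "
                        f"{'left' if cam_x == 0 else 'right'} view (col {c:.1f}, row {r:.1f})"
                    )
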
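import numpy as np
import pytest

from stereovol import (
    CameraIntrinsics,
    SceneSpec,
    ShapePrimitive,
    StereoRig,
    simulation_rig,
)


@pytest.fixture(scope="session")
def reference_rig() -> StereoRig:
    """The deployed device's geometry: f = 3.38 mm, 1.4 um pixels, b = 152.4 mm."""
    cam = CameraIntrinsics(
        focal_length_mm=3.38,
        pixel_size_mm=0.0014,
        principal_point=(1296.0, 972.0),
        image_size=(2592, 1944),
    )
    return StereoRig(left=cam, right=cam, baseline_mm=152.4, rectified=True)


@pytest.fixture(scope="session")
def sim_rig() -> StereoRig:
    return simulation_rig()


@pytest.fixture(scope="session")
def small_rig() -> StereoRig:
    """Small frame for fast matcher tests: f_px = 400, tray disparity = 40 px."""
    return simulation_rig(image_size=(160, 120), focal_length_mm=8.0, pixel_size_mm=0.02)


def make_scene(primitive: ShapePrimitive, **kw) -> SceneSpec:
    kw.setdefault("seed", 3)
    return SceneSpec(primitives=(primitive,), **kw)


@pytest.fixture(scope="session")
def slab_scene() -> SceneSpec:
    return make_scene(
        ShapePrimitive("slab", dict(size_x=100, size_y=100, height=30), position=(76, 0))
    )


@pytest.fixture(scope="session")
def small_slab_scene() -> SceneSpec:
    """Slab sized for the small rig (overlap x in [-95, 247] mm at f_px=400)."""
    return make_scene(
        ShapePrimitive("slab", dict(size_x=120, size_y=120, height=30), position=(76, 0))
    )
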
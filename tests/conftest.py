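import numpy as np
import pytest

from trayvol.rgbd import CameraModel, DepthFrame
from trayvol.solids import make_solid
from trayvol.synth import SceneSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_camera():
    """Toy camera for frame-level unit tests."""
    return CameraModel(focal_length_px=400.0, baseline_mm=75.0, width_px=12, height_px=9)


@pytest.fixture
def flat_frame():
    """12x9 frame of a flat tray plane at 1200 mm."""
    return DepthFrame(np.full((9, 12), 1200.0))


def random_depth_frame(rng, shape=(9, 12), base=1200.0, spread=40.0, invalid_frac=0.0):
    values = base + rng.uniform(-spread, spread, size=shape)
    valid = rng.random(shape) >= invalid_frac
    return DepthFrame(np.where(valid, values, 0.0), valid)


@pytest.fixture
def cap_scene():
    """Single protein-mound scene at kpix = 0.5 mm/px with exact ground truth."""
    solid = make_solid(
        "spherical_cap", radius_mm=60, cap_height_mm=40,
        class_label="chicken", color=(180, 110, 40),
    )
    return render_scene(SceneSpec(solids=(solid,)))
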
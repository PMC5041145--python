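import numpy as np
import pytest

from allphotons import (
    EmulatorConfig,
    KernelModel,
    SceneImage,
    SceneSpec,
    SpaceTimeCube,
    emulate_measurement,
    make_scene,
)
from allphotons.forward_model import ForwardOperator


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_grid():
    """A small measurement geometry: 8 frames of 16 x 17 at 0.5 mm / 4 ps."""
    return SpaceTimeCube(np.zeros((8, 16, 17)), dx=0.5, dy=0.5, dt=4.0)


@pytest.fixture
def small_model(small_grid, rng):
    return KernelModel(f_T=rng.random(small_grid.nt) + 0.2, D=0.01, t0=6.0)


@pytest.fixture
def small_operator(small_model, small_grid):
    return ForwardOperator(
        small_model, small_grid, scene_shape=(16, 17), scene_pitch=0.5
    )


@pytest.fixture(scope="session")
def midi_instance():
    """A mid-size noiseless synthetic measurement of a compact scene,
    rendered through a known kernel — shared by calibration tests."""
    scene = make_scene(
        SceneSpec(kind="point", diameter=4.0, shape=(41, 41))
    )
    config = EmulatorConfig(
        seed=0, nt=96, spatial_shape=(41, 41), psnr_db=float("inf"),
        ballistic_fraction=1e-3,  # identifiable ballistic arrival
    )
    cube, model = emulate_measurement(scene, config)
    return {"scene": scene, "cube": cube, "model": model, "config": config}
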
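"""Blind calibration: f_T, noise floor, t0, and the D line search."""

import numpy as np
import pytest

from allphotons import (
    EmulatorConfig,
    KernelModel,
    SceneSpec,
    SpaceTimeCube,
    calibrate,
    emulate_measurement,
    make_scene,
)
from allphotons.calibration import (
    estimate_D,
    estimate_ft,
    estimate_noise_floor_and_t0,
    normalize_cube,
)
from allphotons.errors import (
    InsufficientSignalError,
    InvalidProfileError,
    NoSignalError,
)
from allphotons.evaluation import add_measurement_noise
from allphotons.forward_model import ForwardOperator, apply_forward


def test_estimate_ft_selects_strongest_pixel_and_floors_at_zero():
    data = np.zeros((6, 4, 4))
    data[:, 1, 2] = [0.0, 1.0, 5.0, 2.0, -0.5, 0.0]
    data[:, 3, 0] = [0.0, 3.0, 3.0, 1.0, 0.0, 0.0]
    cube = SpaceTimeCube(data)
    x0, y0, f_T = estimate_ft(cube)
    assert (x0, y0) == (2, 1)  # peak amplitude 5 beats peak 3
    assert np.all(f_T >= 0)
    x0e, y0e, _ = estimate_ft(cube, stat="energy")
    assert (x0e, y0e) == (2, 1)
    with pytest.raises(NoSignalError):
        estimate_ft(SpaceTimeCube(np.zeros((3, 2, 2))))


def test_estimate_ft_trace_tracks_the_arrival_profile_for_broad_scenes():
    # for a scene much wider than the blur, the strongest pixel's trace
    # is proportional to the generating arrival-time density
    scene = make_scene(SceneSpec(kind="point", diameter=34.0, shape=(41, 41)))
    cube, model = emulate_measurement(
        scene, EmulatorConfig(seed=0, nt=96, spatial_shape=(41, 41),
                              psnr_db=float("inf"))
    )
    _, _, f_T = estimate_ft(cube)
    corr = np.corrcoef(f_T, model.f_T)[0, 1]
    assert corr > 0.99


def test_t0_detection_noiseless_exact():
    data = np.zeros((40, 5, 5))
    data[17:, 2, 2] = 1.0
    floor, t0_frame = estimate_noise_floor_and_t0(SpaceTimeCube(data))
    assert t0_frame == 17


def test_t0_detection_with_noise_and_strong_ballistic_frame(midi_instance):
    scene = midi_instance["scene"]
    config = EmulatorConfig(
        seed=4, nt=96, spatial_shape=(41, 41), psnr_db=60.0,
        ballistic_fraction=1e-2,
    )
    cube, model = emulate_measurement(scene, config)
    _, t0_frame = estimate_noise_floor_and_t0(cube)
    assert t0_frame == cube.frame_index(model.t0)


def test_pure_noise_cube_raises_no_signal(rng):
    noise = rng.normal(0.0, 1.0, size=(32, 21, 21))
    with pytest.raises(NoSignalError):
        estimate_noise_floor_and_t0(SpaceTimeCube(noise))


def test_explicit_dark_region_argument():
    data = np.zeros((10, 3, 3))
    data[0:, 1, 1] = 2.0  # signal from frame 0: no pre-signal frames
    _, t0_frame = estimate_noise_floor_and_t0(
        SpaceTimeCube(data), dark_region=np.zeros(100)
    )
    assert t0_frame == 0


def test_normalize_divides_guards_and_inverts(midi_instance, rng):
    cube, model = midi_instance["cube"], midi_instance["model"]
    norm, valid = normalize_cube(
        cube, model.f_T, equalize_mass=False
    )
    kb = cube.frame_index(model.t0)
    # unguarded frames are exactly the per-frame kernels * scene
    for k in range(kb + 1, cube.nt):
        if valid[k]:
            np.testing.assert_allclose(
                norm.data[k], cube.data[k] / model.f_T[k], atol=1e-8
            )
    # guarded frames zeroed and flagged
    assert not valid[0] and np.all(norm.data[0] == 0)
    # re-multiplication recovers the cube on unguarded frames
    re = norm.data[valid] * model.f_T[valid, None, None]
    np.testing.assert_allclose(re, np.clip(cube.data[valid], 0, None), atol=1e-12)
    with pytest.raises(InvalidProfileError):
        normalize_cube(cube, np.zeros(cube.nt))
    with pytest.raises(InvalidProfileError):
        normalize_cube(cube, np.ones(3))


def test_equalized_frames_share_total_mass(midi_instance):
    cube, model = midi_instance["cube"], midi_instance["model"]
    norm, valid = normalize_cube(cube, model.f_T, equalize_mass=True)
    masses = norm.data[valid].sum(axis=(1, 2))
    np.testing.assert_allclose(masses, masses[0], rtol=1e-9)


def _cube_with_known_d(d_star, psnr_db=float("inf"), seed=0):
    """Fine-pitch instance (0.3 mm pixels) with a small known D."""
    scene = make_scene(
        SceneSpec(kind="point", diameter=3.0, shape=(61, 61), pitch=0.3)
    )
    grid = SpaceTimeCube(np.zeros((128, 61, 61)), dx=0.3, dy=0.3, dt=8.0)
    tau = grid.frame_times() - 8.0
    f_T = np.where(tau > 0, tau * np.exp(-tau / 250.0), 0.0)
    f_T /= f_T.sum()
    model = KernelModel(f_T=f_T, D=d_star, t0=8.0)
    op = ForwardOperator(model, grid, scene_shape=(61, 61), scene_pitch=0.3)
    cube = op.apply(scene)
    if np.isfinite(psnr_db):
        cube = add_measurement_noise(cube, psnr_db, seed=seed)
    return cube, model


def test_estimate_d_recovers_small_diffusion_coefficient():
    cube, model = _cube_with_known_d(5e-4)
    norm, valid = normalize_cube(cube, model.f_T)
    d_hat, trace = estimate_D(norm, cube.frame_index(model.t0), frame_mask=valid)
    assert d_hat == pytest.approx(5e-4, rel=0.10)
    assert len(trace) > 50
    assert min(r for _, r in trace) == pytest.approx(
        dict((d, r) for d, r in trace)[d_hat], abs=1e-12
    )


def test_estimate_d_with_measurement_noise():
    cube, model = _cube_with_known_d(5e-4, psnr_db=50.0, seed=3)
    norm, valid = normalize_cube(cube, np.clip(model.f_T, 0, None))
    d_hat, _ = estimate_D(norm, cube.frame_index(model.t0), frame_mask=valid)
    assert d_hat == pytest.approx(5e-4, rel=0.20)


def test_estimate_d_is_invariant_to_rebinning_and_time_origin(midi_instance):
    from allphotons import rebin_time

    cube = midi_instance["cube"]
    d_full = calibrate(cube).model.D
    d_rebin = calibrate(rebin_time(cube, 2)).model.D
    assert d_rebin == pytest.approx(d_full, rel=0.05)
    shifted = SpaceTimeCube(
        cube.data.copy(), cube.dx, cube.dy, cube.dt, t_start=100.0
    )
    assert calibrate(shifted).model.D == pytest.approx(d_full, rel=1e-9)


def test_estimate_d_requires_usable_pairs():
    data = np.zeros((6, 5, 5))
    data[3, 2, 2] = 1.0
    with pytest.raises(InsufficientSignalError):
        estimate_D(SpaceTimeCube(data), t0_frame=3)


def test_calibrate_round_trip_reproduces_the_measurement(midi_instance):
    scene, cube, model = (
        midi_instance["scene"], midi_instance["cube"], midi_instance["model"],
    )
    report = calibrate(cube)
    assert report.t0_frame == cube.frame_index(model.t0)
    assert report.model.D == pytest.approx(model.D, rel=0.10)
    assert (report.x0, report.y0) == (20, 20)
    # fitted model reproduces the raw measurement up to a global scale
    pred = apply_forward(scene, report.model, cube)
    alpha = float(np.vdot(pred.data, cube.data) / np.vdot(pred.data, pred.data))
    rel = np.linalg.norm(alpha * pred.data - cube.data) / np.linalg.norm(cube.data)
    assert rel < 0.10


def test_calibrate_recovers_parameters_for_random_compact_scenes(rng):
    for _ in range(2):
        mask = np.zeros((41, 41))
        ys, xs = rng.integers(12, 29, 4), rng.integers(12, 29, 4)
        mask[ys, xs] = 1.0
        from allphotons.containers import SceneImage
        from scipy.ndimage import binary_dilation

        scene = SceneImage(binary_dilation(mask, iterations=2).astype(float), 1.0)
        config = EmulatorConfig(
            seed=0, nt=96, spatial_shape=(41, 41), psnr_db=float("inf"),
            ballistic_fraction=1e-3,
        )
        cube, model = emulate_measurement(scene, config)
        report = calibrate(cube)
        assert report.t0_frame == cube.frame_index(model.t0)
        assert report.model.D == pytest.approx(model.D, rel=0.10)


def test_calibrate_is_deterministic(midi_instance):
    a = calibrate(midi_instance["cube"])
    b = calibrate(midi_instance["cube"])
    assert a.model.D == b.model.D and a.t0_frame == b.t0_frame
    np.testing.assert_array_equal(a.model.f_T, b.model.f_T)
    np.testing.assert_array_equal(a.normalized.data, b.normalized.data)
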
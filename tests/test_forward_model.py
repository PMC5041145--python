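"""The time-variant Gaussian forward model and its linear operator."""

import numpy as np
import pytest

from allphotons import KernelModel, SpaceTimeCube, diffusion_kernel_frame
from allphotons.errors import RegistrationError, SizeCapError
from allphotons.forward_model import (
    ForwardOperator,
    delta_frame,
    gaussian_frame,
)


def frame_variance(frame, coords):
    """Per-axis second moment by direct summation."""
    X, Y = np.meshgrid(coords, coords)
    vx = (frame * X * X).sum() / frame.sum()
    vy = (frame * Y * Y).sum() / frame.sum()
    return vx, vy


@pytest.mark.parametrize("d,tau", [(0.01, 40.0), (0.1, 200.0), (0.3, 50.0)])
def test_kernel_frame_is_a_unit_mass_density(d, tau):
    n = int(6 * np.sqrt(2 * d * tau)) * 2 + 21
    grid = SpaceTimeCube(np.zeros((4, n, n)), dx=1.0, dy=1.0, dt=10.0)
    model = KernelModel(f_T=np.ones(4), D=d, t0=10.0)
    w = diffusion_kernel_frame(model, 10.0 + tau, grid)
    assert w.sum() == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_array_equal(w, w[::-1, ::-1])  # central symmetry


def test_kernel_frame_requires_t_after_t0(small_model, small_grid):
    with pytest.raises(ValueError, match="strictly after"):
        diffusion_kernel_frame(small_model, small_model.t0, small_grid)


def test_kernel_variance_grows_linearly_with_time():
    n = 101
    grid = SpaceTimeCube(np.zeros((4, n, n)), dx=0.5, dy=0.5, dt=10.0)
    model = KernelModel(f_T=np.ones(4), D=0.05, t0=0.0)
    coords = grid.x_coords()
    w1 = diffusion_kernel_frame(model, 40.0, grid)
    w2 = diffusion_kernel_frame(model, 90.0, grid)
    v1x, v1y = frame_variance(w1, coords)
    v2x, v2y = frame_variance(w2, coords)
    expected = 2 * 0.05 * (90.0 - 40.0)
    assert v2x - v1x == pytest.approx(expected, rel=0.01)
    assert v2y - v1y == pytest.approx(expected, rel=0.01)


def test_delta_frame_splits_ties_on_even_grids():
    odd = delta_frame(5, 5)
    assert odd[2, 2] == 1.0 and odd.sum() == 1.0
    even = delta_frame(4, 4)
    assert even.sum() == pytest.approx(1.0)
    np.testing.assert_array_equal(even, even[::-1, ::-1])
    assert even[1, 1] == pytest.approx(0.25)


def test_forward_of_center_delta_reproduces_scaled_kernels(small_grid):
    nt = small_grid.nt
    # odd grid so the center pixel is exact
    grid = SpaceTimeCube(np.zeros((nt, 17, 17)), dx=0.5, dy=0.5, dt=4.0)
    model = KernelModel(f_T=np.linspace(0.1, 1.0, nt), D=0.01, t0=6.0)
    op = ForwardOperator(model, grid, scene_shape=(17, 17), scene_pitch=0.5)
    scene = np.zeros((17, 17))
    scene[8, 8] = 1.0
    out = op.apply(scene)
    kb = grid.frame_index(model.t0)
    times = grid.frame_times()
    for k in range(nt):
        if k < kb:
            np.testing.assert_array_equal(out.data[k], 0.0)
            continue
        w = gaussian_frame(17, 17, 0.5, 0.5, 2 * model.D * (times[k] - model.t0))
        np.testing.assert_allclose(out.data[k], model.f_T[k] * w, atol=1e-12)


def test_forward_is_linear(small_operator, rng):
    s1, s2 = rng.random((16, 17)), rng.random((16, 17))
    a, b = 1.7, -0.4
    lhs = small_operator._apply_arr(a * s1 + b * s2)
    rhs = a * small_operator._apply_arr(s1) + b * small_operator._apply_arr(s2)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)
    np.testing.assert_array_equal(small_operator._apply_arr(np.zeros((16, 17))), 0.0)


@pytest.mark.parametrize("pitch_ratio", [1, 2])
def test_adjoint_passes_the_dot_product_test(small_model, pitch_ratio, rng):
    grid = SpaceTimeCube(np.zeros((8, 16, 16)), dx=0.5, dy=0.5, dt=4.0)
    shape = (16 // pitch_ratio, 16 // pitch_ratio)
    op = ForwardOperator(
        small_model, grid, scene_shape=shape, scene_pitch=0.5 * pitch_ratio
    )
    s = rng.random(shape)
    m = rng.random((8, 16, 16))
    lhs = np.vdot(op._apply_arr(s), m)
    rhs = np.vdot(s, op._adjoint_arr(m))
    assert lhs == pytest.approx(rhs, rel=1e-8)
    np.testing.assert_array_equal(op._adjoint_arr(np.zeros((8, 16, 16))), 0.0)


def test_explicit_matrix_matches_implicit_operator(rng):
    grid = SpaceTimeCube(np.zeros((8, 16, 16)), dx=1.0, dy=1.0, dt=10.0)
    model = KernelModel(f_T=rng.random(8) + 0.2, D=0.05, t0=5.0)
    op = ForwardOperator(model, grid, scene_shape=(8, 8), scene_pitch=2.0)
    A = op.matrix()
    assert A.min() > -1e-12  # nonnegative up to FFT roundoff
    s = rng.random((8, 8))
    np.testing.assert_allclose(
        A @ s.ravel(), op._apply_arr(s).ravel(), atol=1e-10
    )


def test_compact_kernel_columns_carry_the_full_point_source_mass(rng):
    # small D keeps every kernel inside the grid, so each unit scene
    # pixel deposits alpha * sum(f_T) of mass wherever it sits
    grid = SpaceTimeCube(np.zeros((6, 17, 17)), dx=1.0, dy=1.0, dt=4.0)
    f_T = rng.random(6) + 0.2
    model = KernelModel(f_T=f_T, D=1e-3, t0=2.0)
    op = ForwardOperator(model, grid, scene_shape=(17, 17))
    A = op.matrix()
    kb = grid.frame_index(model.t0)
    expected = f_T[kb:].sum()
    inner = [
        j for j in range(17 * 17)
        if 4 <= j // 17 <= 12 and 4 <= j % 17 <= 12
    ]
    np.testing.assert_allclose(A[:, inner].sum(axis=0), expected, rtol=1e-6)


def test_matrix_size_cap(small_operator):
    with pytest.raises(SizeCapError):
        small_operator.matrix(entry_cap=10)


def test_lipschitz_matches_dense_svd_and_scales_quadratically(rng):
    grid = SpaceTimeCube(np.zeros((8, 16, 16)), dx=1.0, dy=1.0, dt=10.0)
    f_T = rng.random(8) + 0.2
    m1 = KernelModel(f_T=f_T, D=0.05, t0=5.0)
    op1 = ForwardOperator(m1, grid, scene_shape=(8, 8), scene_pitch=2.0)
    L1 = op1.lipschitz(tol=1e-8, max_iter=500)
    smax2 = np.linalg.svd(op1.matrix(), compute_uv=False)[0] ** 2
    assert L1.converged and L1.value == pytest.approx(smax2, rel=0.01)
    assert L1.value > 0
    m2 = KernelModel(f_T=f_T, D=0.05, t0=5.0, alpha=2.0)
    op2 = ForwardOperator(m2, grid, scene_shape=(8, 8), scene_pitch=2.0)
    assert op2.lipschitz(tol=1e-8, max_iter=500).value == pytest.approx(
        4 * L1.value, rel=1e-3
    )


def test_shift_invariance_of_the_forward_model(rng):
    grid = SpaceTimeCube(np.zeros((6, 33, 33)), dx=1.0, dy=1.0, dt=10.0)
    model = KernelModel(f_T=rng.random(6) + 0.2, D=0.02, t0=5.0)
    op = ForwardOperator(model, grid, scene_shape=(33, 33))
    scene = np.zeros((33, 33))
    scene[10:14, 9:12] = 1.0
    out = op._apply_arr(scene)
    out_shift = op._apply_arr(np.roll(scene, (3, 2), axis=(0, 1)))
    np.testing.assert_allclose(
        np.roll(out, (3, 2), axis=(1, 2))[:, 8:-8, 8:-8],
        out_shift[:, 8:-8, 8:-8],
        atol=1e-9,
    )


def test_registration_errors(small_model, small_grid):
    with pytest.raises(RegistrationError):
        ForwardOperator(small_model, small_grid, scene_shape=(16, 17), scene_pitch=0.7)
    with pytest.raises(RegistrationError):
        ForwardOperator(small_model, small_grid, scene_shape=(5, 5), scene_pitch=0.5)
    op = ForwardOperator(small_model, small_grid, scene_shape=(16, 17), scene_pitch=0.5)
    with pytest.raises(RegistrationError):
        op.apply(np.zeros((4, 4)))
    with pytest.raises(RegistrationError):
        op.adjoint(np.zeros((2, 16, 17)))


def test_kernel_model_validation():
    with pytest.raises(ValueError):
        KernelModel(f_T=np.array([-1.0, 1.0]), D=0.1, t0=0.0)
    with pytest.raises(ValueError):
        KernelModel(f_T=np.ones(4), D=0.0, t0=0.0)
    with pytest.raises(ValueError):
        KernelModel(f_T=np.ones(4), D=0.1, t0=-1.0)
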
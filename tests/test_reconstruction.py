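"""FISTA inversion and the comparison baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from allphotons import KernelModel, SceneImage, SpaceTimeCube, soft_threshold
from allphotons.errors import StepSizeError
from allphotons.forward_model import ForwardOperator
from allphotons.reconstruction import (
    SolverConfig,
    ballistic_init,
    baseline_ballistic,
    baseline_time_average,
    fista,
    pseudoinverse_solve,
)


def test_soft_threshold_definition():
    np.testing.assert_allclose(
        soft_threshold(np.array([3.0, -2.0, 0.5]), 1.0), [2.0, -1.0, 0.0]
    )
    v = np.array([3.0, -2.0, 0.5])
    np.testing.assert_allclose(soft_threshold(v, 0.0), v)
    np.testing.assert_allclose(
        soft_threshold(np.array([-3.0, 2.0]), 1.0, nonneg=True), [0.0, 1.0]
    )
    with pytest.raises(ValueError):
        soft_threshold(v, -1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    hnp.arrays(float, 12, elements=st.floats(-100, 100)),
    st.floats(0, 50),
)
def test_soft_threshold_is_an_l1_contraction(v, tau):
    out = soft_threshold(v, tau)
    assert np.abs(out).sum() <= np.abs(v).sum() + 1e-9
    assert np.all(np.abs(out) <= np.abs(v) + 1e-12)


@pytest.fixture(scope="module")
def oracle_instance():
    rng = np.random.default_rng(0)
    grid = SpaceTimeCube(np.zeros((8, 16, 16)), dx=1.0, dy=1.0, dt=10.0)
    model = KernelModel(f_T=rng.random(8) + 0.2, D=0.05, t0=5.0)
    op = ForwardOperator(model, grid, scene_shape=(8, 8), scene_pitch=2.0)
    s_true = rng.random((8, 8))
    m = op.apply(s_true)
    return {"op": op, "m": m, "s_true": s_true, "A": op.matrix()}


def test_fista_matches_dense_least_squares_without_regularization(oracle_instance):
    op, m, A = oracle_instance["op"], oracle_instance["m"], oracle_instance["A"]
    res = fista(
        op, m, SolverConfig(lam=0.0, max_iters=3000, nonneg=False, tol=None)
    )
    s_ls, *_ = np.linalg.lstsq(A, m.data.ravel(), rcond=None)
    rel = np.linalg.norm(res.scene_hat.data.ravel() - s_ls) / np.linalg.norm(s_ls)
    assert rel < 1e-4


def test_fista_zero_measurement_fixed_point(oracle_instance):
    op = oracle_instance["op"]
    zero = op.grid.with_data(np.zeros_like(op.grid.data))
    res = fista(op, zero, SolverConfig(lam=0.01, max_iters=50))
    np.testing.assert_array_equal(res.scene_hat.data, 0.0)
    assert res.iterations_run == 1  # objective hits zero immediately


def test_fista_objective_descends_and_is_deterministic(oracle_instance):
    op, m = oracle_instance["op"], oracle_instance["m"]
    cfg = SolverConfig(lam=0.01, max_iters=200, tol=None)
    a = fista(op, m, cfg)
    b = fista(op, m, cfg)
    np.testing.assert_array_equal(a.scene_hat.data, b.scene_hat.data)
    trace = a.objective_trace
    assert trace[-1] <= trace[0]
    running_min = np.minimum.accumulate(trace)
    assert np.all(np.diff(running_min) <= 0)
    assert len(trace) == a.iterations_run + 1


def test_fista_oversized_step_raises(oracle_instance):
    op, m = oracle_instance["op"], oracle_instance["m"]
    L = op.lipschitz().value
    with pytest.raises(StepSizeError):
        fista(op, m, SolverConfig(lam=0.0, max_iters=500, step=25.0 / L, tol=None))


def test_regularization_path_shrinks_the_solution(oracle_instance):
    op, m = oracle_instance["op"], oracle_instance["m"]
    l1 = []
    for lam in [1e-4, 1e-3, 1e-2, 1e-1]:
        res = fista(op, m, SolverConfig(lam=lam, max_iters=1500, tol=1e-12))
        l1.append(np.abs(res.scene_hat.data).sum())
    assert all(a >= b - 1e-6 for a, b in zip(l1, l1[1:]))


def test_time_average_baseline_sums_frames(rng):
    data = np.zeros((5, 8, 8))
    data[2, 3, 4] = 2.0
    cube = SpaceTimeCube(data)
    out = baseline_time_average(cube)
    assert out.data[3, 4] == 1.0 and out.data.sum() == 1.0
    shuffled = SpaceTimeCube(data[::-1].copy())
    np.testing.assert_array_equal(
        baseline_time_average(shuffled).data, out.data
    )


def test_ballistic_baseline_returns_one_frame_untouched(rng):
    data = rng.random((6, 8, 8))
    cube = SpaceTimeCube(data)
    out = baseline_ballistic(cube, 2)
    np.testing.assert_array_equal(out.data, data[2])
    other = data.copy()
    other[4] += 10.0
    np.testing.assert_array_equal(
        baseline_ballistic(SpaceTimeCube(other), 2).data, out.data
    )
    init = ballistic_init(cube, 2)
    assert init.data.max() == pytest.approx(1.0)
    assert np.all(init.data >= 0)


def test_pseudoinverse_inverts_square_full_rank(rng):
    A = rng.random((16, 16)) + np.eye(16)
    s_true = rng.random(16)
    out = pseudoinverse_solve(A, A @ s_true, (4, 4))
    np.testing.assert_allclose(out.data.ravel(), s_true, atol=1e-8)


def test_pseudoinverse_residual_orthogonal_to_range(rng):
    base = rng.random((20, 4))
    A = np.hstack([base, base[:, :2]])  # rank deficient
    m = rng.random(20)
    s = pseudoinverse_solve(A, m, (2, 3)).data.ravel()
    residual = A @ s - m
    np.testing.assert_allclose(A.T @ residual, 0.0, atol=1e-8)
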
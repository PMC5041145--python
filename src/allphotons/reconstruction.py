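"""Scene reconstruction: FISTA l1 inversion and comparison baselines.

The normalized measurement is inverted by minimizing

    F(s) = 1/2 || A s - m_bar ||_2^2 + lambda ||s||_1

with FISTA, initialized from the (noisy) ballistic frame so the
iteration starts near the geometrically correct support.  The proximal
step optionally projects to s >= 0 (scenes are physical transmittance
masks).  Baselines: the time-averaged image (no temporal information),
the raw ballistic frame (early-photon gating), and the Moore-Penrose
pseudoinverse on small explicit instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SceneImage, SpaceTimeCube, block_average
from .errors import RegistrationError, StepSizeError
from .forward_model import ForwardOperator

__all__ = [
    "SolverConfig",
    "ReconstructionResult",
    "soft_threshold",
    "fista",
    "baseline_time_average",
    "baseline_ballistic",
    "ballistic_init",
    "pseudoinverse_solve",
]


@dataclass
class SolverConfig:
    """FISTA settings.

    ``lam`` and ``max_iters`` default to the reference values used for
    every scene (lambda = 0.004, 10000 iterations); ``tol`` enables an
    optional early stop on the relative objective change (off by
    default, mirroring the fixed iteration count).  ``step`` overrides
    the automatic 0.95 / L step size.
    """

    lam: float = 0.004
    max_iters: int = 10000
    step: float | None = None
    nonneg: bool = True
    init_mode: str = "ballistic_frame"
    tol: float | None = None
    restart: bool = True  # adaptive (gradient-scheme) momentum restart

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class ReconstructionResult:
    scene_hat: SceneImage
    objective_trace: np.ndarray
    config: SolverConfig
    iterations_run: int


def soft_threshold(v: np.ndarray, tau: float, nonneg: bool = False) -> np.ndarray:
    """Elementwise sign(v) * max(|v| - tau, 0); with ``nonneg`` the
    result is additionally projected onto the nonnegative orthant
    (the proximal map of tau*||.||_1 + indicator(v >= 0))."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(v, dtype=float)
    if nonneg:
        return np.maximum(v - tau, 0.0)
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def fista(
    operator: ForwardOperator,
    m_bar: SpaceTimeCube,
    config: SolverConfig | None = None,
    init: SceneImage | np.ndarray | None = None,
) -> ReconstructionResult:
    """Minimize 1/2 ||A s - m_bar||^2 + lambda ||s||_1 with FISTA.

    The solver is deterministic: fixed inputs and config give
    bit-identical iterates.  Raises :class:`StepSizeError` if the
    objective grows beyond 10x its initial value (step too large).
    """
    if config is None:
        config = SolverConfig()
    m = m_bar.data if isinstance(m_bar, SpaceTimeCube) else np.asarray(m_bar)
    if m.shape != operator.grid.data.shape:
        raise RegistrationError("measurement shape does not match operator")
    if init is None:
        x = np.zeros(operator.scene_shape)
    else:
        x = np.asarray(init.data if isinstance(init, SceneImage) else init, float)
        if x.shape != operator.scene_shape:
            raise RegistrationError("init shape does not match scene grid")
        x = x.copy()

    if config.step is None:
        L = operator.lipschitz().value
        if L <= 0:
            raise StepSizeError("operator norm is zero; nothing to invert")
        step = 0.95 / L
    else:
        step = config.step

    lam = config.lam

    def objective_from(Ax: np.ndarray, s: np.ndarray) -> float:
        r = Ax - m
        return 0.5 * float(np.vdot(r, r)) + lam * float(np.abs(s).sum())

    # By linearity A y = A x + beta (A x - A x_prev), so each iteration
    # needs one forward (at the new iterate, reused for the objective)
    # and one adjoint instead of three operator applications.
    y = x.copy()
    t = 1.0
    Ax = operator._apply_arr(x)
    Ax_prev = Ax
    Ay = Ax
    trace = [objective_from(Ax, x)]
    f0 = trace[0]
    n_run = 0
    for it in range(1, config.max_iters + 1):
        grad = operator._adjoint_arr(Ay - m)
        x_new = soft_threshold(y - step * grad, step * lam, nonneg=config.nonneg)
        if config.restart and float(np.vdot(y - x_new, x_new - x)) > 0.0:
            # adaptive restart: momentum has overshot, reset it
            t = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_new
        y = x_new + beta * (x_new - x)
        Ax_prev, Ax = Ax, operator._apply_arr(x_new)
        Ay = Ax + beta * (Ax - Ax_prev)
        x, t = x_new, t_new
        f = objective_from(Ax, x)
        trace.append(f)
        n_run = it
        if f > 10.0 * max(f0, 1e-300) and f > f0 + 1e-12:
            raise StepSizeError(
                f"objective diverged at iteration {it} "
                f"({f:.3g} vs initial {f0:.3g}); reduce the step size"
            )
        if f == 0.0:
            break
        if config.tol is not None and it > 1:
            prev = trace[-2]
            if abs(prev - f) <= config.tol * max(abs(prev), 1e-300):
                break
    return ReconstructionResult(
        scene_hat=SceneImage(x, operator.scene_pitch),
        objective_trace=np.asarray(trace),
        config=config,
        iterations_run=n_run,
    )


def _to_scene_pitch(
    frame: np.ndarray, cube: SpaceTimeCube, scene_pitch: float | None
) -> tuple[np.ndarray, float]:
    if scene_pitch is None:
        return frame, cube.dx
    ratio = scene_pitch / cube.dx
    r = int(round(ratio))
    if r < 1 or abs(ratio - r) > 1e-9:
        raise RegistrationError(
            "scene pitch must be an integer multiple of the cube pitch"
        )
    return block_average(frame, r), scene_pitch


def baseline_time_average(
    cube: SpaceTimeCube, scene_pitch: float | None = None
) -> SceneImage:
    """Sum over all frames (no temporal information), resampled to scene
    pitch and scaled to unit maximum."""
    img = cube.data.sum(axis=0)
    img, pitch = _to_scene_pitch(img, cube, scene_pitch)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return SceneImage(img, pitch)


def baseline_ballistic(
    cube: SpaceTimeCube, t0_frame: int, scene_pitch: float | None = None
) -> SceneImage:
    """The raw early-photon frame m(., ., t0), resampled to scene pitch.

    No denoising is applied: through thick slabs this frame is
    comparable to the measurement noise, which is exactly what the
    baseline demonstrates.
    """
    frame = cube.data[int(t0_frame)]
    frame, pitch = _to_scene_pitch(frame, cube, scene_pitch)
    return SceneImage(frame, pitch)


def ballistic_init(
    cube: SpaceTimeCube, t0_frame: int, scene_pitch: float | None = None
) -> SceneImage:
    """Ballistic frame prepared as a FISTA starting point: resampled to
    scene pitch, clipped at zero and scaled to unit maximum."""
    img = baseline_ballistic(cube, t0_frame, scene_pitch)
    arr = np.clip(img.data, 0.0, None)
    peak = arr.max()
    if peak > 0:
        arr = arr / peak
    return SceneImage(arr, img.pitch)


def pseudoinverse_solve(
    A: np.ndarray,
    m_vec: np.ndarray,
    scene_shape: tuple[int, int],
    scene_pitch: float = 1.0,
    rcond: float = 1e-10,
) -> SceneImage:
    """Minimum-norm least-squares solution via the Moore-Penrose
    pseudoinverse with singular values below ``rcond * s_max`` cut off."""
    s, *_ = np.linalg.lstsq(A, np.asarray(m_vec, float).ravel(), rcond=rcond)
    return SceneImage(s.reshape(scene_shape), scene_pitch)
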
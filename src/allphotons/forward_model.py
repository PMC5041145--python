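"""Time-variant diffusion forward model and its linear operator.

The measurement of a hidden scene ``s`` through a thick scattering slab
is modelled as

    m(x, y, t) = alpha * f_T(t) * ( W(.,.|t) * s )(x, y)

where ``*`` is 2D convolution, ``f_T(t)`` is the photon arrival-time
density and ``W(x, y | t)`` the spatial arrival density conditioned on
arrival time: a centered isotropic Gaussian whose per-axis variance is
``2 D (t - t0)``, with ``D`` the diffusion coefficient (mm^2/ps) and
``t0`` the ballistic transit-time offset of the slab.  Each discretized
``W`` frame is renormalized to unit mass (all constants, including the
pixel-area factor, are absorbed into ``f_T`` exactly as the
normalization convention requires); the ``t = t0`` frame is the
discrete delta (ballistic) kernel.

:class:`ForwardOperator` applies the model implicitly through cached
FFTs of the per-frame kernels (zero-padded linear convolution, so the
scene is assumed dark outside the field of view), exposes the exact
adjoint needed by gradient-based solvers, and can materialize the dense
matrix ``A`` for small instances (each column the vectorized
measurement of a unit point source).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .containers import SceneImage, SpaceTimeCube, block_average, upsample_scene
from .errors import RegistrationError, SizeCapError

__all__ = [
    "KernelModel",
    "ForwardOperator",
    "LipschitzEstimate",
    "diffusion_kernel_frame",
    "delta_frame",
    "apply_forward",
    "apply_adjoint",
    "build_explicit_matrix",
    "lipschitz_estimate",
]


@dataclass
class KernelModel:
    """Estimated (or ground-truth) forward-model parameters.

    Attributes
    ----------
    f_T : ndarray, shape (nt,)
        Per-time-bin arrival weights, >= 0.
    D : float
        Diffusion coefficient, mm^2/ps (> 0).
    t0 : float
        Ballistic arrival time, ps (>= 0).
    alpha : float
        Global intensity scale (> 0); 1 in the normalized pipeline.
    noise_floor : float
        Sensor noise floor in cube intensity units.
    """

    f_T: np.ndarray
    D: float
    t0: float
    alpha: float = 1.0
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        self.f_T = np.asarray(self.f_T, dtype=float)
        if self.f_T.ndim != 1:
            raise ValueError("f_T must be a 1D per-frame array")
        if np.any(self.f_T < 0):
            raise ValueError("f_T entries must be >= 0")
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def t0_frame(self, cube: SpaceTimeCube) -> int:
        """Index of the time bin containing the ballistic arrival."""
        return cube.frame_index(self.t0)

    def to_dict(self) -> dict:
        return {
            "f_T": [float(v) for v in self.f_T],
            "D_mm2_per_ps": float(self.D),
            "t0_ps": float(self.t0),
            "alpha": float(self.alpha),
            "noise_floor": float(self.noise_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelModel":
        return cls(
            f_T=np.asarray(d["f_T"], dtype=float),
            D=float(d["D_mm2_per_ps"]),
            t0=float(d["t0_ps"]),
            alpha=float(d.get("alpha", 1.0)),
            noise_floor=float(d.get("noise_floor", 0.0)),
        )


def _axis_profile(n: int, pitch: float, var: float) -> np.ndarray:
    x = (np.arange(n) - (n - 1) / 2.0) * pitch
    return np.exp(-(x * x) / (2.0 * var))


def delta_frame(ny: int, nx: int, dy: float = 1.0, dx: float = 1.0) -> np.ndarray:
    """Discrete unit-mass delta at the grid center.

    On even-length axes the center falls between pixels; the mass is
    split equally over the tied nearest pixels, preserving the central
    symmetry W(x, y) = W(-x, -y).
    """
    frame = np.zeros((ny, nx))

    def _center_weights(n: int) -> np.ndarray:
        w = np.zeros(n)
        c = (n - 1) / 2.0
        lo = int(np.floor(c))
        if n % 2:
            w[lo] = 1.0
        else:
            w[lo] = w[lo + 1] = 0.5
        return w

    frame[:] = np.outer(_center_weights(ny), _center_weights(nx))
    return frame


def gaussian_frame(
    ny: int, nx: int, dy: float, dx: float, var: float
) -> np.ndarray:
    """Centered isotropic Gaussian with per-axis variance ``var`` (mm^2),
    discretized on pixel centers and renormalized to unit mass."""
    if var <= 0:
        return delta_frame(ny, nx, dy, dx)
    frame = np.outer(
        _axis_profile(ny, dy, var), _axis_profile(nx, dx, var)
    )
    total = frame.sum()
    if total <= 0:
        raise ValueError("kernel mass vanished; grid/variance mismatch")
    return frame / total


def diffusion_kernel_frame(
    model: KernelModel, t: float, grid: SpaceTimeCube
) -> np.ndarray:
    """The scattering kernel frame W(., .|t) on the grid's spatial axes.

    Requires ``t > t0`` strictly; at ``t == t0`` callers should use
    :func:`delta_frame` (the zero-variance limit on a discrete grid).
    The returned frame sums to 1.
    """
    tau = t - model.t0
    if tau <= 0:
        raise ValueError(
            f"t = {t} ps is not strictly after t0 = {model.t0} ps; "
            "use delta_frame for the ballistic frame"
        )
    ny, nx = grid.spatial_shape
    return gaussian_frame(ny, nx, grid.dy, grid.dx, 2.0 * model.D * tau)


@dataclass
class LipschitzEstimate:
    """Largest eigenvalue of A^T A from power iteration."""

    value: float
    converged: bool
    iterations: int

    def __float__(self) -> float:
        return float(self.value)


class ForwardOperator:
    """Implicit linear operator mapping a scene to a measurement cube.

    Parameters
    ----------
    model : KernelModel
    grid : SpaceTimeCube
        Measurement-geometry template (data ignored).
    scene_shape : (int, int)
        Shape of the scene grid.
    scene_pitch : float, optional
        Scene pixel pitch, mm; must be an integer multiple of the cube
        pitch and tile the cube exactly.  Defaults to the cube pitch.
    include_ft : bool
        If True (raw model) frames are scaled by ``alpha * f_T(t)``;
        if False the operator applies the per-frame kernels ``W`` alone,
        which is the operator acting on f_T-normalized measurements.
    frame_mask : ndarray of bool, optional
        Frames excluded from the model (e.g. guarded frames with no
        usable f_T); masked frames are zero in both apply and adjoint.
    """

    def __init__(
        self,
        model: KernelModel,
        grid: SpaceTimeCube,
        scene_shape: tuple[int, int] | None = None,
        scene_pitch: float | None = None,
        include_ft: bool = True,
        frame_mask: np.ndarray | None = None,
    ) -> None:
        nt, ny, nx = grid.data.shape
        if len(model.f_T) != nt:
            raise RegistrationError(
                f"f_T has {len(model.f_T)} entries but the cube has {nt} frames"
            )
        if abs(grid.dx - grid.dy) > 1e-12:
            raise RegistrationError("anisotropic spatial pitch is not supported")
        if scene_pitch is None:
            scene_pitch = grid.dx
        ratio = scene_pitch / grid.dx
        r = int(round(ratio))
        if r < 1 or abs(ratio - r) > 1e-9:
            raise RegistrationError(
                f"scene pitch {scene_pitch} mm is not an integer multiple of "
                f"the cube pitch {grid.dx} mm"
            )
        if scene_shape is None:
            if ny % r or nx % r:
                raise RegistrationError(
                    "cube spatial shape is not divisible by the pitch ratio"
                )
            scene_shape = (ny // r, nx // r)
        if scene_shape[0] * r != ny or scene_shape[1] * r != nx:
            raise RegistrationError(
                f"scene grid {scene_shape} at pitch ratio {r} does not tile "
                f"the cube's {ny} x {nx} spatial grid"
            )
        self.model = model
        self.grid = grid
        self.scene_shape = tuple(scene_shape)
        self.scene_pitch = float(scene_pitch)
        self.upsample = r
        self.include_ft = bool(include_ft)

        kb = grid.frame_index(model.t0)
        self.t0_frame = kb
        times = grid.frame_times()
        kernels = np.zeros((nt, ny, nx))
        active = np.zeros(nt, dtype=bool)
        for k in range(nt):
            if k < kb:
                continue
            tau = times[k] - model.t0
            if k == kb and tau <= 0:
                # ballistic arrival in the latter half of its bin:
                # zero-variance limit on the discrete grid
                kernels[k] = delta_frame(ny, nx, grid.dy, grid.dx)
            else:
                kernels[k] = gaussian_frame(
                    ny, nx, grid.dy, grid.dx, 2.0 * model.D * tau
                )
            active[k] = True
        if frame_mask is not None:
            frame_mask = np.asarray(frame_mask, dtype=bool)
            if frame_mask.shape != (nt,):
                raise RegistrationError("frame_mask length must equal nt")
            active &= frame_mask
        self.frame_mask = active
        scale = np.where(active, 1.0, 0.0)
        if include_ft:
            scale = scale * model.alpha * model.f_T
        self._scale = scale

        self._Ly = sfft.next_fast_len(2 * ny - 1)
        self._Lx = sfft.next_fast_len(2 * nx - 1)
        self._oy = (ny - 1) // 2
        self._ox = (nx - 1) // 2
        self._Kf = sfft.rfft2(kernels, s=(self._Ly, self._Lx))

    # -- array-level core ------------------------------------------------

    def _apply_arr(self, scene: np.ndarray) -> np.ndarray:
        nt, ny, nx = self.grid.data.shape
        su = upsample_scene(scene, self.upsample)
        Sf = sfft.rfft2(su, s=(self._Ly, self._Lx))
        conv = sfft.irfft2(self._Kf * Sf[None, :, :], s=(self._Ly, self._Lx))
        out = conv[:, self._oy:self._oy + ny, self._ox:self._ox + nx]
        return out * self._scale[:, None, None]

    def _adjoint_arr(self, cube: np.ndarray) -> np.ndarray:
        nt, ny, nx = self.grid.data.shape
        y = cube * self._scale[:, None, None]
        pad = np.zeros((nt, self._Ly, self._Lx))
        pad[:, self._oy:self._oy + ny, self._ox:self._ox + nx] = y
        Yf = sfft.rfft2(pad)
        acc = (np.conj(self._Kf) * Yf).sum(axis=0)
        g = sfft.irfft2(acc, s=(self._Ly, self._Lx))[:ny, :nx]
        r = self.upsample
        if r > 1:
            sy, sx = self.scene_shape
            g = g.reshape(sy, r, sx, r).sum(axis=(1, 3))
        return g

    # -- public API ------------------------------------------------------

    def apply(self, scene: SceneImage | np.ndarray) -> SpaceTimeCube:
        """Forward-project a scene into a measurement cube."""
        arr = scene.data if isinstance(scene, SceneImage) else np.asarray(scene)
        if arr.shape != self.scene_shape:
            raise RegistrationError(
                f"scene shape {arr.shape} != expected {self.scene_shape}"
            )
        g = self.grid
        return SpaceTimeCube(self._apply_arr(arr), g.dx, g.dy, g.dt, g.t_start)

    def adjoint(self, cube: SpaceTimeCube | np.ndarray) -> SceneImage:
        """Exact adjoint of :meth:`apply` (gradient back-projection)."""
        arr = cube.data if isinstance(cube, SpaceTimeCube) else np.asarray(cube)
        if arr.shape != self.grid.data.shape:
            raise RegistrationError(
                f"cube shape {arr.shape} != expected {self.grid.data.shape}"
            )
        return SceneImage(self._adjoint_arr(arr), self.scene_pitch)

    def matrix(self, entry_cap: float = 1e7) -> np.ndarray:
        """Dense matrix A; column j is the vectorized measurement of the
        j-th unit scene pixel (scene raveled row-major, cube raveled
        frame-major then row-major)."""
        n_scene = int(np.prod(self.scene_shape))
        n_cube = int(np.prod(self.grid.data.shape))
        if n_scene * n_cube > entry_cap:
            raise SizeCapError(
                f"explicit matrix would have {n_scene * n_cube:.3g} entries "
                f"(cap {entry_cap:.3g}); use the implicit operator"
            )
        A = np.empty((n_cube, n_scene))
        unit = np.zeros(self.scene_shape)
        for j in range(n_scene):
            unit.flat[j] = 1.0
            A[:, j] = self._apply_arr(unit).ravel()
            unit.flat[j] = 0.0
        return A

    def lipschitz(
        self, tol: float = 1e-5, max_iter: int = 200
    ) -> LipschitzEstimate:
        """Largest eigenvalue of A^T A by power iteration (deterministic:
        starts from the all-ones scene)."""
        x = np.ones(self.scene_shape)
        x /= np.linalg.norm(x)
        lam = 0.0
        for it in range(1, max_iter + 1):
            y = self._adjoint_arr(self._apply_arr(x))
            lam_new = float(np.linalg.norm(y))
            if lam_new == 0.0:
                return LipschitzEstimate(0.0, True, it)
            x = y / lam_new
            if abs(lam_new - lam) <= tol * lam_new:
                return LipschitzEstimate(lam_new, True, it)
            lam = lam_new
        warnings.warn(
            "power iteration did not converge; returning last iterate",
            stacklevel=2,
        )
        return LipschitzEstimate(lam, False, max_iter)


# -- thin functional wrappers -------------------------------------------


def apply_forward(
    scene: SceneImage, model: KernelModel, grid: SpaceTimeCube, **kw
) -> SpaceTimeCube:
    """Apply the raw forward model m = alpha * f_T * (W * s)."""
    op = ForwardOperator(
        model, grid, scene_shape=scene.shape, scene_pitch=scene.pitch, **kw
    )
    return op.apply(scene)


def apply_adjoint(
    cube: SpaceTimeCube,
    model: KernelModel,
    scene_shape: tuple[int, int],
    scene_pitch: float | None = None,
    **kw,
) -> SceneImage:
    op = ForwardOperator(
        model, cube, scene_shape=scene_shape, scene_pitch=scene_pitch, **kw
    )
    return op.adjoint(cube)


def build_explicit_matrix(
    model: KernelModel,
    grid: SpaceTimeCube,
    scene_shape: tuple[int, int],
    scene_pitch: float | None = None,
    entry_cap: float = 1e7,
    **kw,
) -> np.ndarray:
    op = ForwardOperator(
        model, grid, scene_shape=scene_shape, scene_pitch=scene_pitch, **kw
    )
    return op.matrix(entry_cap=entry_cap)


def lipschitz_estimate(operator: ForwardOperator, **kw) -> LipschitzEstimate:
    return operator.lipschitz(**kw)
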
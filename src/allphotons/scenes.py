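"""Synthetic hidden scenes and the end-to-end measurement emulator.

Scenes are binary transmittance masks on a 1 mm grid (71 x 71 by
default, an odd size so the grid has a well-defined center pixel):
a disk "point source", three vertical slits at a given separation, a
bitmap letter, or a wedge whose taper reveals the resolution limit.

The emulator renders the streak-camera measurement of a mask behind a
scattering slab either analytically (the diffusion forward model with
a ground-truth kernel) or empirically (per-frame convolution with a
Monte Carlo PSF), then adds sensor noise at a target measurement PSNR.

Generator defaults mirror the reference acquisition scaled down for
desk-size runs: a 15 mm slab, a 128-frame cube at 1 mm x 1 mm x 8 ps
voxels — the same 1 ns time window as the physical system, which
records 305 x 305 x 512 at 0.3 mm and 2 ps — and measurement PSNR
61.7 dB.  The ballistic fraction defaults to 1e-7 of the total arrival
mass: through ~100 optical depths of scattering the truly unscattered
component is vanishingly small, so the frame at the ballistic transit
time holds signal well below the sensor noise — the regime in which
early-photon gating fails while the diffuse frames still carry the
scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .containers import SceneImage, SpaceTimeCube, upsample_scene
from .errors import GeometryError
from .evaluation import add_measurement_noise
from .forward_model import ForwardOperator, KernelModel
from .mc import simulate_psf
from .phantom import PhantomSpec

__all__ = [
    "SceneSpec",
    "EmulatorConfig",
    "make_scene",
    "analytic_model_for_phantom",
    "emulate_measurement",
    "rebin_time",
    "DEFAULT_PHANTOM",
]

# 15 mm slab with reduced scattering 10 cm^-1, the tissue-phantom regime
DEFAULT_PHANTOM = PhantomSpec.single_layer(
    thickness=15.0, mu_s=66.7, g=0.85, mu_a=0.0
)

# 7 x 9 bitmap glyphs ('.' transparent, '#' opaque mask opening) so letter
# scenes are bit-reproducible without system fonts
_FONT = {
    "A": (
        "..###..",
        ".#...#.",
        "#.....#",
        "#.....#",
        "#######",
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
    ),
    "E": (
        "#######",
        "#......",
        "#......",
        "#......",
        "#####..",
        "#......",
        "#......",
        "#......",
        "#######",
    ),
    "H": (
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
        "#######",
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
    ),
    "T": (
        "#######",
        "...#...",
        "...#...",
        "...#...",
        "...#...",
        "...#...",
        "...#...",
        "...#...",
        "...#...",
    ),
    "U": (
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
        "#.....#",
        ".#...#.",
        "..###..",
    ),
}


@dataclass
class SceneSpec:
    """Parameters of a synthetic hidden mask.

    kind : {"point", "slits", "letter", "wedge", "custom"}
    """

    kind: str = "slits"
    shape: tuple[int, int] = (71, 71)
    pitch: float = 1.0
    # point
    diameter: float = 4.0
    # slits
    count: int = 3
    separation: float = 10.0
    slit_width: float = 2.0
    slit_length: float = 40.0
    # letter
    glyph: str = "A"
    height: float = 45.0
    # wedge
    opening_deg: float = 25.0
    length: float = 50.0
    # custom
    data: np.ndarray | None = None


def _grid_coords(spec: SceneSpec):
    ny, nx = spec.shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spec.pitch
    x = (np.arange(nx) - (nx - 1) / 2.0) * spec.pitch
    return np.meshgrid(x, y)


def make_scene(spec: SceneSpec) -> SceneImage:
    """Render a deterministic binary mask from its specification."""
    ny, nx = spec.shape
    extent_x = nx * spec.pitch
    extent_y = ny * spec.pitch
    X, Y = _grid_coords(spec)

    if spec.kind == "point":
        if spec.diameter > min(extent_x, extent_y):
            raise GeometryError("point diameter exceeds the grid")
        mask = (X * X + Y * Y) <= (spec.diameter / 2.0) ** 2
    elif spec.kind == "slits":
        span = (spec.count - 1) * spec.separation + spec.slit_width
        if span > extent_x or spec.slit_length > extent_y:
            raise GeometryError(
                f"slit pattern ({span:.1f} mm wide) exceeds the grid"
            )
        centers = (np.arange(spec.count) - (spec.count - 1) / 2.0) * spec.separation
        mask = np.zeros(spec.shape, dtype=bool)
        for cx in centers:
            mask |= (np.abs(X - cx) <= spec.slit_width / 2.0) & (
                np.abs(Y) <= spec.slit_length / 2.0
            )
    elif spec.kind == "letter":
        if spec.glyph not in _FONT:
            raise GeometryError(
                f"no glyph {spec.glyph!r}; available: {sorted(_FONT)}"
            )
        bitmap = np.array(
            [[c == "#" for c in row] for row in _FONT[spec.glyph]], dtype=bool
        )
        zoom = max(1, int(round(spec.height / spec.pitch / bitmap.shape[0])))
        big = np.kron(bitmap, np.ones((zoom, zoom), dtype=bool))
        if big.shape[0] > ny or big.shape[1] > nx:
            raise GeometryError("letter height exceeds the grid")
        mask = np.zeros(spec.shape, dtype=bool)
        oy = (ny - big.shape[0]) // 2
        ox = (nx - big.shape[1]) // 2
        mask[oy:oy + big.shape[0], ox:ox + big.shape[1]] = big
    elif spec.kind == "wedge":
        if spec.length > extent_x:
            raise GeometryError("wedge length exceeds the grid")
        half = np.deg2rad(spec.opening_deg) / 2.0
        x_apex = -spec.length / 2.0
        mask = (
            (X >= x_apex)
            & (X <= x_apex + spec.length)
            & (np.abs(Y) <= np.tan(half) * (X - x_apex))
        )
    elif spec.kind == "custom":
        if spec.data is None:
            raise GeometryError("custom scene needs explicit data")
        arr = np.asarray(spec.data, dtype=float)
        if arr.shape != spec.shape:
            raise GeometryError("custom data shape mismatch")
        return SceneImage(arr, spec.pitch)
    else:
        raise GeometryError(f"unknown scene kind {spec.kind!r}")
    return SceneImage(mask.astype(float), spec.pitch)


def slit_centers(spec: SceneSpec) -> np.ndarray:
    """Column indices of the slit centers of a slits scene."""
    nx = spec.shape[1]
    centers_mm = (
        np.arange(spec.count) - (spec.count - 1) / 2.0
    ) * spec.separation
    return centers_mm / spec.pitch + (nx - 1) / 2.0


@dataclass
class EmulatorConfig:
    """End-to-end measurement emulation settings (see module docstring
    for the rationale behind the defaults)."""

    phantom: PhantomSpec = field(default_factory=lambda: DEFAULT_PHANTOM)
    model: KernelModel | None = None  # overrides the phantom-derived model
    nt: int = 128
    spatial_shape: tuple[int, int] | None = None  # defaults to scene shape
    dx: float = 1.0
    dt: float = 8.0
    t_start: float = 0.0
    psnr_db: float = 61.7
    seed: int = 0
    mode: str = "analytic"  # or "mc"
    n_photons: int = 200_000
    ballistic_fraction: float = 1e-7
    tail_power: float = 2.5
    tail_time: float | None = None
    causal_delay_transports: float = 5.0


def analytic_model_for_phantom(
    phantom: PhantomSpec,
    grid: SpaceTimeCube,
    ballistic_fraction: float = 1e-7,
    tail_power: float = 2.5,
    tail_time: float | None = None,
    causal_delay_transports: float = 5.0,
) -> KernelModel:
    """Ground-truth kernel parameters from diffusion theory.

    D = c / (3 mu_s'), with mu_s' the thickness-weighted mean reduced
    scattering coefficient (so layered media reduce to their total
    optical thickness); t0 = L / c is the ballistic transit time.  The
    arrival-time density is a delta spike at t0 carrying
    ``ballistic_fraction`` of the total mass plus a diffuse tail with
    the slab-transmission shape ``t^(-p) * exp(-t_diff / t)`` for
    t > t0 (p = 2.5, t_diff = L^2 / (4 D)): diffuse arrivals rise
    after the ballistic front, peak near ``t_diff / p`` and decay
    algebraically — the familiar time-of-flight profile of a thick
    slab.  Because the diffusion Green's function is acausal right at
    the front (it lets diffuse photons arrive arbitrarily close to
    t0), the tail is further multiplied by ``exp(-t_c / (t - t0))``
    with ``t_c = causal_delay_transports`` transport scattering times
    — diffuse arrivals need a few direction-randomizing scatterings'
    worth of excess path, which leaves the early-photon frame at the
    sensor noise level of the emulated system, as in the physical
    measurement.
    """
    mus_red_mm = phantom.mean_reduced_mu_s() / 10.0
    if mus_red_mm <= 0:
        raise ValueError("phantom must scatter (mu_s' > 0)")
    D = phantom.speed / (3.0 * mus_red_mm)
    t0 = phantom.ballistic_time
    L = phantom.total_thickness
    if tail_time is None:
        tail_time = L * L / (4.0 * D)
    t_c = causal_delay_transports / (mus_red_mm * phantom.speed)
    times = grid.frame_times()
    tau = times - t0
    with np.errstate(divide="ignore"):
        tail = np.where(
            tau > 0,
            np.power(np.maximum(times, 1e-300), -tail_power)
            * np.exp(-tail_time / np.maximum(times, 1e-300))
            * np.exp(-t_c / np.maximum(tau, 1e-300)),
            0.0,
        )
    total = tail.sum()
    if total <= 0:
        raise ValueError("time window ends before the diffuse tail arrives")
    f_T = tail * (1.0 - ballistic_fraction) / total
    f_T[grid.frame_index(t0)] += ballistic_fraction
    return KernelModel(f_T=f_T, D=D, t0=t0, alpha=1.0, noise_floor=0.0)


def _grid_template(scene: SceneImage, config: EmulatorConfig) -> SpaceTimeCube:
    shape = config.spatial_shape or scene.shape
    return SpaceTimeCube(
        np.zeros((config.nt, *shape)),
        dx=config.dx,
        dy=config.dx,
        dt=config.dt,
        t_start=config.t_start,
    )


def emulate_measurement(
    scene: SceneImage,
    config: EmulatorConfig | None = None,
    psf=None,
) -> tuple[SpaceTimeCube, KernelModel]:
    """Render the noisy space-time measurement of a hidden scene.

    Returns the measurement cube and the generating kernel model (for
    recovery tests).  In ``"mc"`` mode each frame is the scene
    convolved with the corresponding Monte Carlo PSF frame and the
    returned model carries the empirical f_T with theory values of
    (D, t0); pass a precomputed ``psf`` (:class:`~allphotons.mc.McPsf`)
    to reuse one simulation across several scenes.
    """
    if config is None:
        config = EmulatorConfig()
    grid = _grid_template(scene, config)
    if config.mode == "analytic":
        model = config.model or analytic_model_for_phantom(
            config.phantom,
            grid,
            ballistic_fraction=config.ballistic_fraction,
            tail_power=config.tail_power,
            tail_time=config.tail_time,
            causal_delay_transports=config.causal_delay_transports,
        )
        op = ForwardOperator(
            model, grid, scene_shape=scene.shape, scene_pitch=scene.pitch
        )
        cube = op.apply(scene)
    elif config.mode == "mc":
        if psf is None:
            psf = simulate_psf(
                config.phantom, config.n_photons, grid, seed=config.seed
            )
        mass = psf.cube.data.sum()
        if mass <= 0:
            raise ValueError("Monte Carlo PSF is empty; increase n_photons")
        psf_data = psf.cube.data / mass
        r = int(round(scene.pitch / grid.dx))
        scene_up = upsample_scene(scene.data, r)
        data = fftconvolve(
            psf_data, scene_up[None, :, :], mode="same", axes=(1, 2)
        )
        cube = grid.with_data(np.clip(data, 0.0, None))
        mus_red_mm = config.phantom.mean_reduced_mu_s() / 10.0
        model = KernelModel(
            f_T=psf_data.sum(axis=(1, 2)),
            D=config.phantom.speed / (3.0 * mus_red_mm),
            t0=config.phantom.ballistic_time,
        )
    else:
        raise ValueError(f"unknown emulation mode {config.mode!r}")
    cube = add_measurement_noise(cube, config.psnr_db, seed=config.seed)
    return cube, model


def rebin_time(cube: SpaceTimeCube, factor: int) -> SpaceTimeCube:
    """Sum consecutive frames in groups of ``factor`` (a slower sensor
    integrating the same photon stream).  Trailing frames that do not
    fill a complete group are dropped; total mass of the kept frames is
    conserved and dt is multiplied by the factor."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("rebin factor must be a positive integer")
    if factor == 1:
        return cube.copy()
    nt = (cube.nt // factor) * factor
    data = cube.data[:nt].reshape(nt // factor, factor, *cube.spatial_shape)
    return SpaceTimeCube(
        data.sum(axis=1), cube.dx, cube.dy, cube.dt * factor, cube.t_start
    )
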
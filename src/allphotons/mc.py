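"""Monte Carlo random-walk photon transport through layered scattering slabs.

Photons are launched at the origin of the near face travelling along +z.
Free paths are exponential with mean 1/mu_s of the current layer, new
directions are drawn from the Henyey-Greenstein phase function, and
absorption attenuates the photon weight continuously along the path
(no Russian roulette, so the weight ledger is exact: transmitted +
backscattered + absorbed + truncated weight equals the number launched
to floating tolerance).  Transmitted photons are binned into an
empirical space-time point-spread function.

The per-photon loop is compiled with numba; a single simulation seed
makes the whole batch reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .containers import SpaceTimeCube
from .phantom import PhantomSpec

__all__ = [
    "PhotonRecord",
    "McPsf",
    "sample_hg_cosine",
    "trace_photon",
    "simulate_psf",
    "FATE_NAMES",
]

FATE_NAMES = ("transmitted", "backscattered", "absorbed", "truncated")
_TRANSMITTED, _BACKSCATTERED, _ABSORBED, _TRUNCATED = 0, 1, 2, 3


def sample_hg_cosine(g, u):
    """Scattering-angle cosine(s) drawn from the Henyey-Greenstein phase
    function via its analytic inverse CDF.

    Parameters
    ----------
    g : float
        Anisotropy factor, the mean cosine of the scattering angle;
        must satisfy ``|g| <= 1``.  ``g = 0`` is isotropic scattering.
    u : float or ndarray
        Uniform variate(s) in [0, 1).

    Returns
    -------
    cos(theta) with the same shape as ``u``, in [-1, 1].
    """
    if abs(g) > 1:
        raise ValueError("anisotropy g must lie in [-1, 1]")
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-8:
        out = 2.0 * u - 1.0
    else:
        term = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - term * term) / (2.0 * g)
    return np.clip(out, -1.0, 1.0)


@dataclass(frozen=True)
class PhotonRecord:
    """Outcome of a single photon random walk.

    ``exit_x``/``exit_y`` are the lateral coordinates (mm) at the last
    position, ``exit_time`` the accumulated time of flight (ps, path
    length divided by the in-medium speed of light), ``weight`` the
    surviving weight in (0, 1], and ``fate`` one of ``transmitted``,
    ``backscattered``, ``absorbed`` or ``truncated``.
    """

    exit_x: float
    exit_y: float
    exit_time: float
    weight: float
    fate: str
    n_scatter: int


@dataclass
class McPsf:
    """Empirical space-time PSF from binned transmitted photons."""

    cube: SpaceTimeCube
    n_launched: int
    n_transmitted: int
    seed: int
    weight_totals: dict
    exit_x: np.ndarray | None = None
    exit_y: np.ndarray | None = None
    exit_time: np.ndarray | None = None
    exit_weight: np.ndarray | None = None


@njit(cache=True)
def _hg_cosine_scalar(g, u):
    if abs(g) < 1e-8:
        c = 2.0 * u - 1.0
    else:
        term = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        c = (1.0 + g * g - term * term) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _trace_batch(
    n_photons,
    zb,          # layer boundary depths, length n_layers + 1, mm
    mus_mm,      # per-layer scattering coefficient, mm^-1
    g_l,         # per-layer anisotropy
    mua_mm,      # per-layer absorption coefficient, mm^-1
    speed,       # mm / ps
    t_max,       # ps
    max_steps,
    weight_min,
    seed,
):
    np.random.seed(seed)
    n_layers = len(mus_mm)
    ex = np.zeros(n_photons)
    ey = np.zeros(n_photons)
    et = np.zeros(n_photons)
    ew = np.zeros(n_photons)
    fate = np.zeros(n_photons, dtype=np.int8)
    nsc = np.zeros(n_photons, dtype=np.int64)
    absorbed = np.zeros(n_photons)

    for i in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        tof = 0.0
        li = 0
        steps = 0
        f = -1
        while f < 0:
            steps += 1
            if steps > max_steps:
                f = _TRUNCATED
                break
            u = np.random.random()
            if u < 1e-300:
                u = 1e-300
            s_opt = -np.log(u)
            # propagate this optical depth, possibly across layer interfaces
            while True:
                mus = mus_mm[li]
                if mus > 0.0:
                    d = s_opt / mus
                else:
                    d = np.inf
                if uz > 1e-12:
                    db = (zb[li + 1] - z) / uz
                elif uz < -1e-12:
                    db = (zb[li] - z) / uz
                else:
                    db = np.inf
                if d == np.inf and db == np.inf:
                    f = _TRUNCATED
                    break
                if d <= db:
                    x += ux * d
                    y += uy * d
                    z += uz * d
                    tof += d / speed
                    if mua_mm[li] > 0.0:
                        w2 = w * np.exp(-mua_mm[li] * d)
                        absorbed[i] += w - w2
                        w = w2
                    break  # scatter at the new position
                else:
                    x += ux * db
                    y += uy * db
                    tof += db / speed
                    s_opt -= db * mus
                    if mua_mm[li] > 0.0:
                        w2 = w * np.exp(-mua_mm[li] * db)
                        absorbed[i] += w - w2
                        w = w2
                    if uz > 0.0:
                        li += 1
                        if li >= n_layers:
                            z = zb[n_layers]
                            f = _TRANSMITTED
                            break
                        z = zb[li]
                    else:
                        z = zb[li]
                        li -= 1
                        if li < 0:
                            f = _BACKSCATTERED
                            break
            if f >= 0:
                break
            if tof > t_max:
                f = _TRUNCATED
                break
            # scatter: HG polar angle, uniform azimuth
            nsc[i] += 1
            cost = _hg_cosine_scalar(g_l[li], np.random.random())
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            phi = 2.0 * np.pi * np.random.random()
            cosp = np.cos(phi)
            sinp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                uz_n = -sint * cosp * den + uz * cost
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm
            if w < weight_min:
                absorbed[i] += w
                w = 0.0
                f = _ABSORBED
                break
        ex[i] = x
        ey[i] = y
        et[i] = tof
        ew[i] = w
        fate[i] = f
    return ex, ey, et, ew, fate, nsc, absorbed


def _phantom_arrays(phantom: PhantomSpec):
    zb = phantom.boundaries()
    mus = np.array([l.mu_s / 10.0 for l in phantom.layers])  # cm^-1 -> mm^-1
    g = np.array([l.g for l in phantom.layers])
    mua = np.array([l.mu_a / 10.0 for l in phantom.layers])
    return zb, mus, g, mua


def trace_photon(
    phantom: PhantomSpec,
    seed: int,
    t_max: float = np.inf,
    max_steps: int = 100_000,
    weight_min: float = 0.0,
) -> PhotonRecord:
    """Trace a single photon through the phantom and report its fate."""
    zb, mus, g, mua = _phantom_arrays(phantom)
    ex, ey, et, ew, fate, nsc, _ = _trace_batch(
        1, zb, mus, g, mua, phantom.speed, t_max, max_steps, weight_min, seed
    )
    return PhotonRecord(
        exit_x=float(ex[0]),
        exit_y=float(ey[0]),
        exit_time=float(et[0]),
        weight=float(ew[0]),
        fate=FATE_NAMES[int(fate[0])],
        n_scatter=int(nsc[0]),
    )


def trace_batch(
    phantom: PhantomSpec,
    n_photons: int,
    seed: int,
    t_max: float = np.inf,
    max_steps: int = 100_000,
    weight_min: float = 0.0,
):
    """Trace ``n_photons`` and return raw per-photon arrays
    (exit_x, exit_y, exit_time, weight, fate code, scatter count,
    absorbed weight)."""
    zb, mus, g, mua = _phantom_arrays(phantom)
    return _trace_batch(
        int(n_photons), zb, mus, g, mua, phantom.speed, t_max, max_steps,
        weight_min, int(seed),
    )


def simulate_psf(
    phantom: PhantomSpec,
    n_photons: int,
    grid: SpaceTimeCube,
    seed: int,
    t_max: float | None = None,
    max_steps: int = 100_000,
    keep_records: bool = False,
) -> McPsf:
    """Launch ``n_photons`` and bin transmitted photons into a PSF cube.

    Parameters
    ----------
    grid : SpaceTimeCube
        Geometry template; its data are ignored, only the shape and
        pitches are used.
    t_max : float, optional
        In-flight truncation time, ps.  Defaults to the end of the
        grid's time window (photons that could never land in the cube
        are recorded as truncated instead of being traced forever).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    nt, ny, nx = grid.data.shape
    if t_max is None:
        t_max = grid.t_start + nt * grid.dt
    ex, ey, et, ew, fate, nsc, absorbed = trace_batch(
        phantom, n_photons, seed, t_max=t_max, max_steps=max_steps
    )
    trans = fate == _TRANSMITTED
    data = np.zeros((nt, ny, nx))
    if trans.any():
        ix = np.rint(ex[trans] / grid.dx + (nx - 1) / 2.0).astype(int)
        iy = np.rint(ey[trans] / grid.dy + (ny - 1) / 2.0).astype(int)
        ik = np.floor((et[trans] - grid.t_start) / grid.dt).astype(int)
        ok = (
            (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            & (ik >= 0) & (ik < nt)
        )
        np.add.at(data, (ik[ok], iy[ok], ix[ok]), ew[trans][ok])
    else:
        warnings.warn(
            "no transmitted photons; the PSF cube is empty", stacklevel=2
        )
    totals = {
        name: float(ew[fate == code].sum())
        for code, name in enumerate(FATE_NAMES)
    }
    totals["absorbed"] += float(absorbed.sum())
    psf = McPsf(
        cube=SpaceTimeCube(data, grid.dx, grid.dy, grid.dt, grid.t_start),
        n_launched=int(n_photons),
        n_transmitted=int(trans.sum()),
        seed=int(seed),
        weight_totals=totals,
    )
    if keep_records:
        psf.exit_x = ex[trans]
        psf.exit_y = ey[trans]
        psf.exit_time = et[trans]
        psf.exit_weight = ew[trans]
    return psf
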
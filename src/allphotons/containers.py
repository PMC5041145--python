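"""In-memory containers for scenes and space-time measurements.

Conventions used throughout the package (stated once, fixed):

* A measurement cube ``m(x, y, t)`` is stored as an array of shape
  ``(nt, ny, nx)`` — one 2D frame per time bin, frames first so that a
  multi-frame TIFF maps directly onto the array.
* Spatial coordinates are centered: pixel ``i`` along an axis of length
  ``n`` sits at ``(i - (n - 1) / 2) * pitch`` so that ``(x, y) = (0, 0)``
  is the center of the grid (the center of the phantom face).
* Frame ``k`` represents the time-bin ``[t_start + k*dt, t_start +
  (k+1)*dt)``; its representative time is the bin center.
* Lexicographic vectorization is ``array.ravel()`` on the ``(nt, ny, nx)``
  layout: row-major over ``(y, x)`` within a frame, frames outermost.

Units are millimetres and picoseconds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SceneImage", "SpaceTimeCube", "upsample_scene", "block_average"]


def _centered_coords(n: int, pitch: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * pitch


@dataclass
class SceneImage:
    """A 2D nonnegative image of the hidden scene s(x', y').

    Parameters
    ----------
    data : ndarray, shape (ny, nx)
        Scene intensities; nonnegative for physical masks.
    pitch : float
        Pixel pitch in mm (the hidden masks are reconstructed at 1 mm).
    """

    data: np.ndarray
    pitch: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SceneImage data must be 2D")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def x_coords(self) -> np.ndarray:
        return _centered_coords(self.data.shape[1], self.pitch)

    def y_coords(self) -> np.ndarray:
        return _centered_coords(self.data.shape[0], self.pitch)

    def copy(self) -> "SceneImage":
        return SceneImage(self.data.copy(), self.pitch)


@dataclass
class SpaceTimeCube:
    """A space-time measurement m(x, y, t).

    Attributes
    ----------
    data : ndarray, shape (nt, ny, nx)
        Per-frame intensities.  Raw noisy cubes may hold negative values;
        after preprocessing (noise clipping / normalization) entries are
        nonnegative.
    dx, dy : float
        Spatial pitch, mm.
    dt : float
        Time-bin width, ps.
    t_start : float
        Time of the leading edge of frame 0, ps.
    """

    data: np.ndarray
    dx: float = 1.0
    dy: float = 1.0
    dt: float = 2.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SpaceTimeCube data must be 3D (nt, ny, nx)")
        if min(self.dx, self.dy, self.dt) <= 0:
            raise ValueError("dx, dy, dt must all be > 0")

    @property
    def nt(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame_times(self) -> np.ndarray:
        """Bin-center times of every frame, ps."""
        return self.t_start + (np.arange(self.nt) + 0.5) * self.dt

    def frame_index(self, t: float) -> int:
        """Index of the bin containing time ``t`` (clipped to range)."""
        k = int(np.floor((t - self.t_start) / self.dt))
        return int(np.clip(k, 0, self.nt - 1))

    def x_coords(self) -> np.ndarray:
        return _centered_coords(self.data.shape[2], self.dx)

    def y_coords(self) -> np.ndarray:
        return _centered_coords(self.data.shape[1], self.dy)

    def copy(self) -> "SpaceTimeCube":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "SpaceTimeCube":
        return replace(self, data=np.asarray(data, dtype=float))


def upsample_scene(scene: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling by an integer factor (pixel replication)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("upsampling factor must be a positive integer")
    if factor == 1:
        return np.asarray(scene, dtype=float)
    return np.kron(np.asarray(scene, dtype=float), np.ones((factor, factor)))


def block_average(image: np.ndarray, factor: int) -> np.ndarray:
    """Average over non-overlapping ``factor x factor`` blocks.

    The adjoint of :func:`upsample_scene` up to the ``factor**2`` scale;
    used to resample measurement-pitch frames to scene pitch.
    """
    image = np.asarray(image, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ValueError("block factor must be a positive integer")
    if factor == 1:
        return image
    ny, nx = image.shape
    if ny % factor or nx % factor:
        raise ValueError("image shape must be divisible by the block factor")
    return image.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))
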
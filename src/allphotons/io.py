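"""File formats: measurement cubes as multi-frame TIFF with a JSON
sidecar, scenes as grayscale TIFF/PNG, models and configs as JSON/YAML.

A cube ``m.tif`` is written frame-per-page in float32 alongside
``m.json`` holding the grid geometry (``dx_mm``, ``dy_mm``, ``dt_ps``,
``t_start_ps``) and any extra metadata; reading without the sidecar
falls back to unit pitches with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .containers import SceneImage, SpaceTimeCube
from .errors import ConfigError, FormatError
from .forward_model import KernelModel

__all__ = [
    "read_cube",
    "write_cube",
    "read_scene",
    "write_scene",
    "read_config",
    "read_model",
    "write_model",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(path, cube: SpaceTimeCube, metadata: dict | None = None) -> None:
    """Write a cube as a multi-frame float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, cube.data.astype(np.float32))
    meta = {
        "dx_mm": cube.dx,
        "dy_mm": cube.dy,
        "dt_ps": cube.dt,
        "t_start_ps": cube.t_start,
    }
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_cube(path) -> SpaceTimeCube:
    """Read a multi-frame TIFF cube and its geometry sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path} does not hold uniform 2D frames")
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(
            f"no sidecar {sidecar.name}; assuming unit pitches", stacklevel=2
        )
        meta = {}
    return SpaceTimeCube(
        np.asarray(data, dtype=float),
        dx=float(meta.get("dx_mm", 1.0)),
        dy=float(meta.get("dy_mm", 1.0)),
        dt=float(meta.get("dt_ps", 1.0)),
        t_start=float(meta.get("t_start_ps", 0.0)),
    )


def write_scene(path, scene: SceneImage) -> None:
    """Write a scene as grayscale TIFF (float32, lossless) or PNG
    (16-bit, min-max scaled)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, scene.data.astype(np.float32))
    elif path.suffix.lower() == ".png":
        a = scene.data
        hi = a.max()
        scaled = (a / hi * 65535.0).astype(np.uint16) if hi > 0 else np.zeros_like(a, np.uint16)
        iio.imwrite(path, scaled)
    else:
        raise FormatError(f"unsupported scene format {path.suffix!r}")
    meta = {"pitch_mm": scene.pitch}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_scene(path) -> SceneImage:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        data = np.asarray(iio.imread(path), dtype=float)
    else:
        raise FormatError(f"unsupported scene format {path.suffix!r}")
    if data.ndim != 2:
        raise FormatError(f"{path} is not a single grayscale image")
    sidecar = _sidecar(path)
    pitch = 1.0
    if sidecar.exists():
        pitch = float(json.loads(sidecar.read_text()).get("pitch_mm", 1.0))
    else:
        warnings.warn(
            f"no sidecar {sidecar.name}; assuming 1 mm pitch", stacklevel=2
        )
    return SceneImage(np.asarray(data, dtype=float), pitch)


_CONFIG_DEFAULTS = {"lambda": 0.004, "max_iters": 10000, "nonneg": True}
_CONFIG_KEYS = {
    "lambda", "max_iters", "nonneg", "step", "tol", "init_mode", "seed",
    "psnr_db", "mode", "n_photons", "ballistic_fraction", "phantom",
    "nt", "dx", "dt", "t_start",
}


def read_config(path) -> dict:
    """Read a JSON/YAML config, validate keys and apply defaults
    (missing ``lambda`` falls back to 0.004, logged via warning)."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} does not hold a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, default in _CONFIG_DEFAULTS.items():
        if key not in cfg:
            warnings.warn(
                f"config missing {key!r}; using default {default}",
                stacklevel=2,
            )
            cfg[key] = default
    return cfg


def write_model(path, model: KernelModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model(path) -> KernelModel:
    return KernelModel.from_dict(json.loads(Path(path).read_text()))
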
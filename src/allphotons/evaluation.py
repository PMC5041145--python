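"""Quantitative evaluation: image-quality metrics, slit resolvability,
and measurement-noise injection.

PSNR and SSIM are computed after min-max scaling both images to [0, 1]
(reconstructions from different methods live on arbitrary intensity
scales), with the reference image defining the peak.  Resolvability
uses a Rayleigh-style operational criterion: peaks along the feature
axis count as resolved when the valley between adjacent peaks drops by
at least a set fraction of the lower peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.metrics import structural_similarity

from .containers import SceneImage, SpaceTimeCube

__all__ = [
    "MetricsReport",
    "psnr",
    "ssim",
    "count_resolved_peaks",
    "match_slit_peaks",
    "add_measurement_noise",
]


@dataclass
class MetricsReport:
    psnr_db: float
    ssim: float
    method: str = ""
    resolved_peaks: int | None = None


def _as_array(img) -> np.ndarray:
    return np.asarray(img.data if isinstance(img, SceneImage) else img, float)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def psnr(reference, estimate) -> float:
    """Peak signal-to-noise ratio, dB.

    Both images are min-max scaled to [0, 1] first; the peak is the
    reference maximum (1 after scaling).  Identical images return
    ``inf``.  Note PSNR is symmetric under exchanging the images only
    when their scaled peaks coincide (they do here by construction,
    but the reference still defines the peak by contract).
    """
    ref, est = _as_array(reference), _as_array(estimate)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must share a grid")
    if not np.any(ref > ref.min()):
        raise ValueError("reference image is constant")
    ref, est = _minmax(ref), _minmax(est)
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def ssim(reference, estimate) -> float:
    """Mean structural similarity over the image, clipped to [0, 1].

    Single-scale SSIM with the reference constants: Gaussian window
    sigma = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1 after min-max
    scaling.
    """
    ref, est = _as_array(reference), _as_array(estimate)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must share a grid")
    kwargs = {}
    if min(ref.shape) < 11:
        # Gaussian window at sigma 1.5 spans 11 px; shrink for tiny images
        kwargs["win_size"] = max(3, min(ref.shape) - (1 - min(ref.shape) % 2))
    value = structural_similarity(
        _minmax(ref),
        _minmax(est),
        data_range=1.0,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
        **kwargs,
    )
    return float(np.clip(value, 0.0, 1.0))


def _resolved_peak_indices(
    profile: np.ndarray,
    dip_criterion: float,
    height_frac: float,
    smooth_sigma: float,
):
    """Indices of dip-resolved peaks of a 1D profile (None if empty).

    Local maxima below ``height_frac`` of the profile maximum are
    ignored; adjacent maxima whose connecting valley drops by less
    than ``dip_criterion`` of the lower peak are merged, weakest dip
    first.
    """
    profile = profile - profile.min()
    if not np.any(profile > 0):
        return None, profile
    if smooth_sigma > 0:
        profile = gaussian_filter1d(profile, smooth_sigma)
    idx, _ = find_peaks(profile, plateau_size=1)
    heights = profile[idx]
    keep = heights >= height_frac * profile.max()
    idx = list(idx[keep])
    heights = list(heights[keep])
    while len(idx) > 1:
        dips = []
        for i in range(len(idx) - 1):
            valley = profile[idx[i]:idx[i + 1] + 1].min()
            lower = min(heights[i], heights[i + 1])
            dips.append((lower - valley) / lower if lower > 0 else 0.0)
        worst = int(np.argmin(dips))
        if dips[worst] >= dip_criterion:
            break
        drop = worst if heights[worst] <= heights[worst + 1] else worst + 1
        del idx[drop], heights[drop]
    return idx, profile


def _projection(recon, axis: int, region) -> tuple[np.ndarray, int]:
    arr = _as_array(recon)
    profile = arr.sum(axis=0 if axis == 1 else 1)
    offset = 0
    if region is not None:
        offset = int(region[0])
        profile = profile[offset:int(region[1])]
    return profile, offset


def count_resolved_peaks(
    recon,
    axis: int = 1,
    region: tuple[int, int] | None = None,
    dip_criterion: float = 0.2,
    height_frac: float = 0.25,
    smooth_sigma: float = 1.0,
) -> int:
    """Count features resolved along one axis of a reconstruction.

    The image is projected (summed) onto ``axis`` (1 = x, features
    varying across columns), optionally restricted to ``region``
    (index bounds along that axis), lightly smoothed at the scene-pixel
    scale, and local maxima are found.  Peaks below ``height_frac`` of
    the strongest peak are ignored; two adjacent peaks count as
    resolved only if the valley between them drops by at least
    ``dip_criterion`` of the lower peak, otherwise they merge.  The
    result is invariant to global intensity scaling.

    Returns 0 for an empty image and 1 for a nonzero image with no
    resolvable structure (e.g. a uniform or single-blob profile).
    """
    profile, _ = _projection(recon, axis, region)
    if not np.any(profile != 0):
        return 0
    if np.ptp(profile) == 0:
        return 1  # uniform nonzero profile: one unresolvable feature
    idx, _prof = _resolved_peak_indices(
        profile, dip_criterion, height_frac, smooth_sigma
    )
    if not idx:
        return 1
    return len(idx)


def match_slit_peaks(
    recon,
    centers: np.ndarray,
    tol: float = 1.0,
    axis: int = 1,
    region: tuple[int, int] | None = None,
    dip_criterion: float = 0.2,
    height_frac: float = 0.25,
    smooth_sigma: float = 1.0,
) -> int:
    """Number of expected slit positions recovered at the correct
    location.

    Runs the same dip-criterion peak finding as
    :func:`count_resolved_peaks` and counts how many of the expected
    ``centers`` (pixel indices along the projection axis) are matched
    by a resolved peak within ``tol`` pixels, each peak matching at
    most one slit.  A noise-dominated image scores low even when it
    contains many spurious peaks: what matters is recovering the
    correct locations.
    """
    profile, offset = _projection(recon, axis, region)
    idx, _prof = _resolved_peak_indices(
        profile, dip_criterion, height_frac, smooth_sigma
    )
    if not idx:
        return 0
    positions = np.asarray(idx, dtype=float) + offset
    matched = 0
    used: set[int] = set()
    for c in np.asarray(centers, dtype=float):
        cands = [
            i for i, p in enumerate(positions)
            if abs(p - c) <= tol and i not in used
        ]
        if cands:
            best = min(cands, key=lambda i: abs(positions[i] - c))
            used.add(best)
            matched += 1
    return matched


def add_measurement_noise(
    cube: SpaceTimeCube,
    target_psnr_db: float,
    seed: int,
    clip: bool = False,
) -> SpaceTimeCube:
    """Add seeded Gaussian sensor noise at a target measurement PSNR.

    The noise std sigma satisfies ``10 log10(peak^2 / sigma^2) =
    target_psnr_db`` with peak the cube maximum.  By default the noisy
    cube is returned unclipped so the realized PSNR matches the target
    exactly; pass ``clip=True`` to floor at zero (the preprocessing
    steps clip anyway).  ``target_psnr_db = inf`` returns an unchanged
    copy.
    """
    if not np.isfinite(target_psnr_db):
        return cube.copy()
    peak = float(cube.data.max())
    if peak <= 0:
        raise ValueError("cube has no signal to set a PSNR against")
    sigma = peak * 10.0 ** (-target_psnr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = cube.data + rng.normal(0.0, sigma, size=cube.data.shape)
    if clip:
        noisy = np.clip(noisy, 0.0, None)
    return cube.with_data(noisy)
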
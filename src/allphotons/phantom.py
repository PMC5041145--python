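"""Scattering-slab descriptions.

A phantom is an ordered stack of homogeneous layers; light enters the
near face (z = 0) travelling along +z and exits the far face
(z = total thickness).  Optical properties follow the tissue-optics
convention: scattering coefficient mu_s and absorption coefficient mu_a
in cm^-1, anisotropy factor g = <cos theta> of the single-scattering
angle.  The slab is index-matched to its surroundings (no boundary
refraction or reflection is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

C_MM_PER_PS = 0.299792458  # vacuum speed of light

__all__ = ["Layer", "PhantomSpec", "C_MM_PER_PS"]


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab layer.

    thickness : mm; mu_s, mu_a : cm^-1; g : dimensionless in [-1, 1].
    """

    thickness: float
    mu_s: float
    g: float = 0.0
    mu_a: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if self.mu_s < 0 or self.mu_a < 0:
            raise ValueError("mu_s and mu_a must be >= 0")
        if abs(self.g) > 1:
            raise ValueError("anisotropy g must lie in [-1, 1]")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), cm^-1."""
        return self.mu_s * (1.0 - self.g)


@dataclass(frozen=True)
class PhantomSpec:
    """An ordered stack of scattering layers.

    The default refractive index of 1.0 means photons travel at the
    vacuum speed of light; time of flight is path length / (c / n).
    """

    layers: tuple[Layer, ...]
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")

    @classmethod
    def single_layer(
        cls,
        thickness: float,
        mu_s: float,
        g: float = 0.0,
        mu_a: float = 0.0,
        refractive_index: float = 1.0,
    ) -> "PhantomSpec":
        return cls((Layer(thickness, mu_s, g, mu_a),), refractive_index)

    @property
    def total_thickness(self) -> float:
        """Total slab thickness, mm (sum over layers)."""
        return float(sum(l.thickness for l in self.layers))

    @property
    def speed(self) -> float:
        """Speed of light inside the medium, mm/ps."""
        return C_MM_PER_PS / self.refractive_index

    @property
    def ballistic_time(self) -> float:
        """Straight-through transit time of the slab, ps."""
        return self.total_thickness / self.speed

    def mean_reduced_mu_s(self) -> float:
        """Thickness-weighted mean reduced scattering coefficient, cm^-1."""
        total = self.total_thickness
        return float(
            sum(l.thickness * l.mu_s_reduced for l in self.layers) / total
        )

    def boundaries(self) -> np.ndarray:
        """Layer interface depths [0, z1, ..., L], mm."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness for l in self.layers])]
        )

    def to_dict(self) -> dict:
        return {
            "layers": [
                {
                    "thickness_mm": l.thickness,
                    "mu_s_cm": l.mu_s,
                    "g": l.g,
                    "mu_a_cm": l.mu_a,
                }
                for l in self.layers
            ],
            "n": self.refractive_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        layers = tuple(
            Layer(
                thickness=float(ld["thickness_mm"]),
                mu_s=float(ld["mu_s_cm"]),
                g=float(ld.get("g", 0.0)),
                mu_a=float(ld.get("mu_a_cm", 0.0)),
            )
            for ld in d["layers"]
        )
        return cls(layers, refractive_index=float(d.get("n", 1.0)))
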
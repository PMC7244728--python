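"""Clinical refraction <-> power-vector algebra.

A sphero-cylindrical refraction (sphere S, cylinder C <= 0, axis alpha in
degrees) maps to the orthogonal dioptric components

    M   = S + C/2
    J0  = -(C/2) * cos(2 alpha)
    J45 = -(C/2) * sin(2 alpha)

M is the spherical equivalent; J0/J45 are the Jackson cross-cylinder
components at 0/90 deg and 45/135 deg.  Negative-cylinder convention
throughout; axis lives in [0, 180) and is stored as 0 when C = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Refraction",
    "PowerVector",
    "refraction_to_power_vector",
    "power_vector_to_refraction",
    "quantize_max_plus",
]


@dataclass(frozen=True)
class Refraction:
    sphere: float  # D
    cylinder: float  # D, <= 0 (negative-cylinder convention)
    axis: float  # degrees in [0, 180); 0 when cylinder == 0

    def __post_init__(self) -> None:
        if self.cylinder > 0:
            raise ValueError("cylinder must be <= 0 (negative-cylinder convention)")
        if not (0 <= self.axis < 180):
            raise ValueError("axis must lie in [0, 180)")
        if self.cylinder == 0 and self.axis != 0:
            raise ValueError("axis must be stored as 0 when cylinder is 0")

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + self.cylinder / 2.0


@dataclass(frozen=True)
class PowerVector:
    M: float
    J0: float
    J45: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.M, self.J0, self.J45))):
            raise ValueError("power-vector components must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.M, self.J0, self.J45)


def refraction_to_power_vector(r: Refraction) -> PowerVector:
    a = math.radians(r.axis)
    half_c = r.cylinder / 2.0
    return PowerVector(
        M=r.sphere + half_c,
        J0=-half_c * math.cos(2 * a),
        J45=-half_c * math.sin(2 * a),
    )


def power_vector_to_refraction(p: PowerVector) -> Refraction:
    """Inverse map; round-trips exactly on the valid domain.

    C = -2*sqrt(J0^2 + J45^2); with -C/2 = sqrt(J0^2 + J45^2) >= 0 the
    forward map reads J0 = (-C/2) cos 2a, J45 = (-C/2) sin 2a, so
    alpha = atan2(J45, J0)/2 mapped into [0, 180); S = M - C/2.
    """
    c = -2.0 * math.hypot(p.J0, p.J45)
    if c == 0.0:
        return Refraction(sphere=p.M, cylinder=0.0, axis=0.0)
    axis = math.degrees(0.5 * math.atan2(p.J45, p.J0)) % 180.0
    return Refraction(sphere=p.M - c / 2.0, cylinder=c, axis=axis)


def _round_half_up(x: float, step: float) -> float:
    # exact midpoints resolve toward +infinity
    return math.floor(x / step + 0.5) * step


def quantize_max_plus(r: Refraction, step: float = 0.25) -> Refraction:
    """Round to the clinical prescription grid under the maximum-plus rule.

    Sphere and cylinder snap to the nearest multiple of ``step``; exact
    midpoints resolve toward the more positive sphere and the
    smaller-magnitude cylinder (both are round-half-up since C <= 0).  The
    axis rounds to the nearest degree; a refraction whose cylinder rounds to
    zero stores axis 0.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    sphere = _round_half_up(r.sphere, step)
    cylinder = min(_round_half_up(r.cylinder, step), 0.0)
    if cylinder == 0.0:
        axis = 0.0
    else:
        axis = float(round(r.axis)) % 180.0
    return Refraction(sphere=sphere, cylinder=cylinder, axis=axis)
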
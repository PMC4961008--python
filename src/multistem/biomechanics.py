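"""Bending moment at the base of leaning and uprising stems.

The stem is a line of distributed mass under gravity.  With the origin at
the stem base and gravity vertical, the bending-moment magnitude is

    M = integral_0^L  rho * g * pi * r(s)^2 * x(s)  ds      [N m]

where ``s`` is arc length along the stem, ``r(s)`` the local radius and
``x(s)`` the horizontal offset of arc position ``s`` from the base.  Two
stem paths are modelled:

* ``straight`` — a straight stem leaning at a fixed angle from the
  vertical, ``x(s) = s sin(theta)``;
* ``uprising`` — a stem that leans at ``theta`` until its horizontal offset
  reaches a cutoff (default 1 m) and then grows straight up, so
  ``x(s) = min(s sin(theta), cutoff)``.  The bend is a sharp corner.

Branches and foliage are excluded from the mass, so these moments are lower
bounds for a stem carrying a canopy.  This module works in SI units
(metres, kg, N m), unlike the cm-based architecture modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from scipy.integrate import quad

__all__ = [
    "StemPath",
    "TaperedStem",
    "radius_profile",
    "horizontal_offset",
    "bending_moment",
]

DEFAULT_WOOD_DENSITY = 600.0  # kg m^-3
DEFAULT_GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class StemPath:
    """Spatial course of a stem of total arc length ``total_length`` (m)."""

    kind: str  # "straight" | "uprising"
    lean_angle: float  # degrees from the vertical, in [0, 90)
    total_length: float  # m
    horizontal_cutoff: float = 1.0  # m; uprising paths only

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "uprising"):
            raise ValueError(f"unknown path kind {self.kind!r}")
        if not 0 <= self.lean_angle < 90:
            raise ValueError(
                f"lean_angle must lie in [0, 90) degrees, got {self.lean_angle}"
            )
        if self.total_length < 0:
            raise ValueError("total_length must be >= 0")
        if self.horizontal_cutoff <= 0:
            raise ValueError("horizontal_cutoff must be > 0")


@dataclass(frozen=True)
class TaperedStem:
    """A stem path with a taper, density and gravity, ready to integrate.

    ``taper=None`` selects the conical profile: radius linear from
    ``max(b * L, r_tip)`` at the base to ``r_tip`` at the tip, the same rule
    the architecture modules use (here in metres).  A custom taper
    (e.g. a Niklas–Spatz profile with user-supplied constants) may be
    passed as a callable ``r(s) -> m``.
    """

    path: StemPath
    b: float = 0.0075
    r_tip: float = 0.001  # m
    taper: Optional[Callable[[float], float]] = None
    wood_density: float = DEFAULT_WOOD_DENSITY  # kg m^-3
    gravity: float = DEFAULT_GRAVITY  # m s^-2

    def __post_init__(self) -> None:
        if self.taper is None and (self.b <= 0 or self.r_tip <= 0):
            raise ValueError("b and r_tip must be positive")
        if self.wood_density <= 0 or self.gravity <= 0:
            raise ValueError("wood_density and gravity must be positive")


def radius_profile(s: float, stem: TaperedStem) -> float:
    """Stem radius (m) at arc position ``s`` from the base."""
    length = stem.path.total_length
    if not 0 <= s <= length:
        raise ValueError(f"s={s} outside [0, {length}]")
    if stem.taper is not None:
        return stem.taper(s)
    r_base = max(stem.b * length, stem.r_tip)
    if length == 0:
        return r_base
    return r_base + (stem.r_tip - r_base) * (s / length)


def horizontal_offset(s: float, path: StemPath) -> float:
    """Horizontal distance (m) of arc position ``s`` from the stem base."""
    x = s * math.sin(math.radians(path.lean_angle))
    if path.kind == "uprising":
        return min(x, path.horizontal_cutoff)
    return x


def bending_moment(stem: TaperedStem) -> float:
    """Gravitational bending-moment magnitude about the stem base, N m.

    Quadrature of ``rho g pi r(s)^2 x(s)`` with the uprising-path corner
    supplied as a breakpoint; relative error <= 1e-8.  Exactly 0 for a
    vertical stem.
    """
    path = stem.path
    length = path.total_length
    if length == 0 or path.lean_angle == 0:
        return 0.0
    rho_g_pi = stem.wood_density * stem.gravity * math.pi

    def integrand(s: float) -> float:
        r = radius_profile(s, stem)
        return rho_g_pi * r * r * horizontal_offset(s, path)

    points = None
    if path.kind == "uprising":
        s_bend = path.horizontal_cutoff / math.sin(math.radians(path.lean_angle))
        if 0 < s_bend < length:
            points = [s_bend]
    moment, _ = quad(
        integrand, 0.0, length, points=points, epsrel=1e-10, epsabs=0.0, limit=200
    )
    return moment
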
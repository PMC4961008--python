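"""Closed-form geometry of truncated-cone (frustum) stem segments.

Every stem and branch in the model is an idealised solid of revolution: a
truncated cone with basal radius ``r_base`` tapering to tip radius
``r_tip_seg`` over its length, degenerating to a cylinder when the two radii
coincide.  All lengths are centimetres; areas cm^2; volumes cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Segment",
    "basal_radius",
    "frustum_volume",
    "frustum_lateral_area",
]


@dataclass(frozen=True)
class Segment:
    """One stem or branch segment.

    Attributes
    ----------
    length : float
        Segment length in cm (>= 0).
    r_base : float
        Basal radius in cm; must satisfy ``r_base >= r_tip_seg > 0``.
    r_tip_seg : float
        Tip radius in cm.
    """

    length: float
    r_base: float
    r_tip_seg: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"segment length must be >= 0, got {self.length}")
        if not self.r_tip_seg > 0:
            raise ValueError(f"tip radius must be > 0, got {self.r_tip_seg}")
        if self.r_base < self.r_tip_seg:
            raise ValueError(
                f"basal radius {self.r_base} smaller than tip radius {self.r_tip_seg}"
            )


def basal_radius(length: float, b: float, r_tip: float) -> float:
    """Basal radius of a stem or branch of given length.

    The radius is proportional to length (``b * length``) except that it is
    floored at ``r_tip``: a segment too short for the proportional rule to
    exceed the tip radius is a cylinder of radius ``r_tip``.

    Parameters
    ----------
    length : float
        Segment length, cm (>= 0).
    b : float
        Ratio of basal radius to length (dimensionless, > 0).
    r_tip : float
        Tip radius, cm (> 0).
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if b <= 0 or r_tip <= 0:
        raise ValueError("b and r_tip must be positive")
    return max(b * length, r_tip)


def frustum_volume(seg: Segment) -> float:
    """Volume of a truncated cone, cm^3.

    ``V = (pi * L / 3) * (R^2 + R*r + r^2)``; reduces to ``pi r^2 L`` for a
    cylinder and to 0 at zero length.
    """
    r1, r2 = seg.r_base, seg.r_tip_seg
    return math.pi * seg.length / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def frustum_lateral_area(seg: Segment) -> float:
    """Lateral (side) surface area of a truncated cone, cm^2.

    Uses the slant height ``sqrt(L^2 + (R - r)^2)``; end caps and the basal
    disk are excluded, since the quantity stands for bark/epidermis area.
    For the slenderness ratios used here (b ~ 0.0075) the slant correction
    relative to ``pi (R + r) L`` is below 1e-5.  Zero at zero length (a
    degenerate segment has no side surface).
    """
    if seg.length == 0:
        return 0.0
    r1, r2 = seg.r_base, seg.r_tip_seg
    slant = math.hypot(seg.length, r1 - r2)
    return math.pi * (r1 + r2) * slant
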
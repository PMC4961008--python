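"""Recursive branching architecture of model trees and shrubs.

A plant is ``n`` identical stems.  A stem of length ``h`` carries ``a``
child branches, each of which carries ``a`` children of its own, and so on;
child length is a fixed fraction ``p`` of the parent's once the parent is
longer than the branching threshold ``l_min``.  To keep the volume function
continuous, children are born at parent length ``(2/3) l_min`` with length 0
and grow linearly until the parent reaches ``l_min`` (where they attain
``p * l_min``), after which they track ``p * parent``.  Because every child
is strictly shorter than its parent (``p < 1``) the recursion terminates.

Each segment is a truncated cone: basal radius ``b * length`` floored at
``r_tip`` (proportional mode), or derived from the Niklas–Spatz
height–diameter allometry ``L = k5 * D^(2/3) - k6`` (niklas_spatz mode).
All trait totals (volume, surface area, basal cross-section, twig count)
are sums over the resulting generations, times ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

from .geometry import Segment, basal_radius, frustum_lateral_area, frustum_volume

__all__ = [
    "PlantParams",
    "NiklasSpatzParams",
    "SegmentGeneration",
    "child_length",
    "enumerate_generations",
    "plant_volume",
    "plant_surface_area",
    "basal_cross_section_total",
    "sprout_area",
    "twig_count",
    "stem_length_from_diameter_ns",
    "diameter_from_stem_length_ns",
]

RAMP_START_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class NiklasSpatzParams:
    """Coefficients of the height–diameter allometry ``L = k5 D^(2/3) - k6``.

    ``k5`` (cm^(1/3)) and ``k6`` (cm) are empirical constants; they are not
    fixed by this package and must be supplied by the user when
    ``radius_mode='niklas_spatz'`` is selected.
    """

    k5: float
    k6: float = 0.0

    def __post_init__(self) -> None:
        if self.k5 <= 0:
            raise ValueError(f"k5 must be > 0, got {self.k5}")


@dataclass(frozen=True)
class PlantParams:
    """Architectural parameter set for one plant (tree or shrub).

    Defaults are the reference parameterisation used throughout:
    ``a=2, p=0.5, l_min=20 cm, r_tip=0.1 cm, b=0.0075``; a tree is ``n=1``,
    a shrub ``n >= 2``.
    """

    n: int = 1
    a: int = 2
    p: float = 0.5
    l_min: float = 20.0
    r_tip: float = 0.1
    b: float = 0.0075
    radius_mode: str = "proportional"
    ns: Optional[NiklasSpatzParams] = None
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"n must be an integer >= 1, got {self.n}")
        if self.a < 0 or int(self.a) != self.a:
            raise ValueError(f"a must be an integer >= 0, got {self.a}")
        if not 0 < self.p < 1:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.l_min <= 0 or self.r_tip <= 0 or self.b <= 0:
            raise ValueError("l_min, r_tip and b must be positive")
        if self.radius_mode not in ("proportional", "niklas_spatz"):
            raise ValueError(f"unknown radius_mode {self.radius_mode!r}")
        if self.radius_mode == "niklas_spatz" and self.ns is None:
            raise ValueError("niklas_spatz mode requires NiklasSpatzParams")


@dataclass(frozen=True)
class SegmentGeneration:
    """All segments at one branching depth (identical by symmetry)."""

    depth: int
    count_per_stem: int
    length: float
    r_base: float


def child_length(parent_length: float, p: float, l_min: float) -> float:
    """Length of a child branch given its parent's length.

    Zero below the birth threshold ``(2/3) l_min``; a linear ramp from 0 to
    ``p * l_min`` as the parent grows from ``(2/3) l_min`` to ``l_min``;
    proportional (``p * parent``) beyond.  Continuous everywhere.
    """
    if parent_length < 0:
        raise ValueError(f"parent_length must be >= 0, got {parent_length}")
    start = RAMP_START_FRACTION * l_min
    if parent_length <= start:
        return 0.0
    if parent_length < l_min:
        # ramp: 0 at start, p*l_min at l_min
        return p * l_min * (parent_length - start) / (l_min - start)
    return p * parent_length


def stem_length_from_diameter_ns(diameter: float, ns: NiklasSpatzParams) -> float:
    """Niklas–Spatz stem length ``L = k5 D^(2/3) - k6`` (cm), clamped at 0."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    length = ns.k5 * diameter ** (2.0 / 3.0) - ns.k6
    return max(length, 0.0)


def diameter_from_stem_length_ns(length: float, ns: NiklasSpatzParams) -> float:
    """Inverse of :func:`stem_length_from_diameter_ns` (cm)."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if length + ns.k6 < 0:
        raise ValueError(
            f"length {length} outside the valid range for k6={ns.k6}"
        )
    return ((length + ns.k6) / ns.k5) ** 1.5


def segment_basal_radius(length: float, params: PlantParams) -> float:
    """Basal radius of a stem or branch of given length under ``params``.

    The same rule (including the ``r_tip`` floor) applies to stems and
    branches alike.
    """
    if params.radius_mode == "niklas_spatz":
        assert params.ns is not None
        radius = diameter_from_stem_length_ns(length, params.ns) / 2.0
        return max(radius, params.r_tip)
    return basal_radius(length, params.b, params.r_tip)


def enumerate_generations(
    stem_length: float, params: PlantParams
) -> List[SegmentGeneration]:
    """All branching generations of a single stem, outermost last.

    Depth 0 is the stem itself; generation ``d`` holds ``a**d`` segments per
    stem.  Enumeration stops when child length reaches 0, which the ramp
    guarantees in finitely many steps.  Returns an empty list for a plant of
    zero stem length.
    """
    if stem_length < 0:
        raise ValueError(f"stem_length must be >= 0, got {stem_length}")
    generations: List[SegmentGeneration] = []
    length = stem_length
    count = 1
    depth = 0
    while length > 0:
        generations.append(
            SegmentGeneration(
                depth=depth,
                count_per_stem=count,
                length=length,
                r_base=segment_basal_radius(length, params),
            )
        )
        if params.a == 0:
            break
        length = child_length(length, params.p, params.l_min)
        count *= params.a
        depth += 1
    return generations


def _segment(gen: SegmentGeneration, params: PlantParams) -> Segment:
    return Segment(gen.length, gen.r_base, params.r_tip)


def plant_volume(stem_length: float, params: PlantParams) -> float:
    """Total above-ground woody volume of the plant, cm^3.

    ``n`` times the sum over generations of segment count times frustum
    volume.  Strictly increasing and continuous in ``stem_length``,
    including across the ramp joints at ``(2/3) l_min`` and ``l_min``.
    """
    total = 0.0
    for gen in enumerate_generations(stem_length, params):
        total += gen.count_per_stem * frustum_volume(_segment(gen, params))
    return params.n * total


def plant_surface_area(stem_length: float, params: PlantParams) -> float:
    """Total lateral surface (bark/epidermis) area of stems and branches, cm^2.

    Vascular-cambium area and stem-photosynthetic area are modelled by this
    same quantity.
    """
    total = 0.0
    for gen in enumerate_generations(stem_length, params):
        total += gen.count_per_stem * frustum_lateral_area(_segment(gen, params))
    return params.n * total


def basal_cross_section_total(stem_length: float, params: PlantParams) -> float:
    """Total cross-sectional area at the stem bases, cm^2 (``n pi r_base^2``)."""
    if stem_length < 0:
        raise ValueError(f"stem_length must be >= 0, got {stem_length}")
    if stem_length == 0:
        return 0.0
    r = segment_basal_radius(stem_length, params)
    return params.n * math.pi * r * r


def sprout_area(
    stem_length: float, params: PlantParams, stem_fraction: float = 0.25
) -> float:
    """Bark area available for basal sprouting, cm^2.

    Lateral area of the basal ``stem_fraction`` of each stem only (branches
    excluded); the stem's radius is interpolated linearly from its basal
    radius to ``r_tip``.
    """
    if not 0 < stem_fraction <= 1:
        raise ValueError(f"stem_fraction must lie in (0, 1], got {stem_fraction}")
    if stem_length < 0:
        raise ValueError(f"stem_length must be >= 0, got {stem_length}")
    if stem_length == 0:
        return 0.0
    r_base = segment_basal_radius(stem_length, params)
    r_cut = r_base + stem_fraction * (params.r_tip - r_base)
    piece = Segment(stem_fraction * stem_length, r_base, r_cut)
    return params.n * frustum_lateral_area(piece)


def twig_count(stem_length: float, params: PlantParams) -> int:
    """Number of twigs: segments of the outermost (deepest) generation.

    Equals ``n`` when the plant has no branches (the stems themselves are
    the outermost tips) and 0 for a plant of zero length.
    """
    generations = enumerate_generations(stem_length, params)
    if not generations:
        return 0
    return params.n * generations[-1].count_per_stem
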
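"""Height-from-volume inversion and shrub-vs-tree trait comparisons.

The model's volume functions V(h) are continuous, strictly increasing and
piecewise smooth (kinks where branch generations are born), so the height at
a given above-ground woody volume is found by bracketing root finding.
Comparisons evaluate a trait for a tree and a shrub holding the woody volume
fixed, the central device of the model: at equal volume a shrub trades
height for multiplicity, gaining cross-sectional, bark and twig quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .architecture import (
    PlantParams,
    basal_cross_section_total,
    plant_surface_area,
    plant_volume,
    sprout_area,
    twig_count,
)

__all__ = [
    "TRAITS",
    "ComparisonResult",
    "height_from_volume",
    "compare_trait",
    "curve_sample",
    "default_volume_grid",
]

#: Trait evaluators: name -> f(stem_length, params).
TRAITS: Dict[str, Callable[[float, PlantParams], float]] = {
    "height": lambda h, params: h,
    "cross_section": basal_cross_section_total,
    "surface_area": plant_surface_area,
    "sprout_area": sprout_area,
    "twig_count": lambda h, params: float(twig_count(h, params)),
}


@dataclass(frozen=True)
class ComparisonResult:
    """Shrub-vs-tree value of one trait at a common woody volume.

    ``percent_greater = 100 * (shrub_value - tree_value) / tree_value``.
    The shrub is evaluated at volume ``g_s * volume`` (growth-rate ratio
    ``g_s``, default 1: equal growth).
    """

    volume: float
    trait: str
    tree_value: float
    shrub_value: float
    n: int
    g_s: float = 1.0

    @property
    def percent_greater(self) -> float:
        return 100.0 * (self.shrub_value - self.tree_value) / self.tree_value


def height_from_volume(v: float, params: PlantParams, rtol: float = 1e-12) -> float:
    """Solve ``plant_volume(h, params) = v`` for the stem length h (cm).

    The root is unique by strict monotonicity; the bracket is found by
    geometric expansion and refined with Brent's method.  The residual
    satisfies ``|V(h) - v| / v <= 1e-10`` for any positive ``v``.
    """
    if v <= 0:
        raise ValueError(f"volume must be > 0, got {v}")
    hi = 1.0
    while plant_volume(hi, params) < v:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            raise RuntimeError("bracket expansion failed")
    h = brentq(
        lambda x: plant_volume(x, params) - v,
        0.0,
        hi,
        xtol=1e-13,
        rtol=max(rtol, 4 * np.finfo(float).eps),
    )
    return float(h)


def compare_trait(
    trait: str,
    v: float,
    shrub: PlantParams,
    tree: PlantParams,
    g_s: float = 1.0,
) -> ComparisonResult:
    """Compare one trait between a shrub and a tree at woody volume ``v``.

    Both heights are solved numerically (the shrub at ``g_s * v``), the
    trait is evaluated for each plant, and the percent difference is
    reported relative to the tree.
    """
    if trait not in TRAITS:
        raise KeyError(
            f"unknown trait {trait!r}; choose from {sorted(TRAITS)}"
        )
    if v <= 0:
        raise ValueError(f"volume must be > 0, got {v}")
    evaluate = TRAITS[trait]
    h_tree = height_from_volume(v, tree)
    h_shrub = height_from_volume(g_s * v, shrub)
    return ComparisonResult(
        volume=v,
        trait=trait,
        tree_value=evaluate(h_tree, tree),
        shrub_value=evaluate(h_shrub, shrub),
        n=shrub.n,
        g_s=g_s,
    )


def default_volume_grid(
    v_min: float = 1.0, v_max: float = 1000.0, num: int = 200
) -> np.ndarray:
    """Log-spaced woody-volume grid (cm^3) used for curve tables."""
    return np.geomspace(v_min, v_max, num)


def curve_sample(
    trait: str,
    v_grid: Sequence[float],
    tree: PlantParams,
    shrubs: Iterable[PlantParams],
) -> pd.DataFrame:
    """Trait-versus-volume curves for a tree and a set of shrubs.

    Returns a tidy table with columns ``volume_cm3, plant_label, n, trait,
    value`` — one row per (volume, plant) pair — from which each trait
    panel (height, cross-section, surface area, twig count) can be plotted.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.ndim != 1 or len(v_grid) == 0:
        raise ValueError("v_grid must be a non-empty 1-D sequence")
    if np.any(v_grid <= 0) or np.any(np.diff(v_grid) <= 0):
        raise ValueError("v_grid must be positive and strictly increasing")
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}; choose from {sorted(TRAITS)}")
    evaluate = TRAITS[trait]
    plants: List[PlantParams] = [tree, *shrubs]
    rows = []
    for plant in plants:
        label = plant.label or ("tree" if plant.n == 1 else f"shrub_n{plant.n}")
        for v in v_grid:
            h = height_from_volume(float(v), plant)
            rows.append(
                {
                    "volume_cm3": float(v),
                    "plant_label": label,
                    "n": plant.n,
                    "trait": trait,
                    "value": evaluate(h, plant),
                }
            )
    return pd.DataFrame(rows, columns=["volume_cm3", "plant_label", "n", "trait", "value"])
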
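import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multistem.architecture import (
    NiklasSpatzParams,
    PlantParams,
    basal_cross_section_total,
    child_length,
    diameter_from_stem_length_ns,
    enumerate_generations,
    plant_surface_area,
    plant_volume,
    sprout_area,
    stem_length_from_diameter_ns,
    twig_count,
)
from multistem.geometry import Segment, frustum_lateral_area, frustum_volume


class TestChildLength:
    @pytest.mark.parametrize(
        "parent, expected",
        [
            (10.0, 0.0),         # below the birth threshold 2/3 * 20
            (20.0, 10.0),        # exactly l_min -> p * l_min
            (40.0, 20.0),        # proportional regime
            (50.0 / 3.0, 5.0),   # midpoint of the linear ramp
        ],
    )
    def test_piecewise_values(self, parent, expected):
        assert child_length(parent, 0.5, 20.0) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 200))
    @settings(max_examples=200)
    def test_continuity_and_bound(self, parent):
        """child length is continuous, bounded by p*parent, and non-decreasing."""
        val = child_length(parent, 0.5, 20.0)
        assert 0.0 <= val <= 0.5 * parent + 1e-12
        eps = 1e-7
        nearby = child_length(parent + eps, 0.5, 20.0)
        assert abs(nearby - val) < 1e-5

    def test_negative_parent_rejected(self):
        with pytest.raises(ValueError):
            child_length(-1.0, 0.5, 20.0)


class TestEnumerateGenerations:
    def test_unbranched_plant(self):
        gens = enumerate_generations(10.0, PlantParams())
        assert len(gens) == 1
        assert gens[0].count_per_stem == 1 and gens[0].length == 10.0

    def test_single_branching(self):
        gens = enumerate_generations(20.0, PlantParams())
        assert [(g.count_per_stem, g.length) for g in gens] == [(1, 20.0), (2, 10.0)]

    def test_deep_proportional_chain(self):
        gens = enumerate_generations(80.0, PlantParams())
        assert [g.length for g in gens] == [80.0, 40.0, 20.0, 10.0]
        assert [g.count_per_stem for g in gens] == [1, 2, 4, 8]

    def test_counts_are_powers_of_a(self):
        for a in (2, 3):
            gens = enumerate_generations(160.0, PlantParams(a=a))
            assert [g.count_per_stem for g in gens] == [a**d for d in range(len(gens))]

    def test_terminates_for_any_height(self):
        gens = enumerate_generations(1e6, PlantParams())
        assert gens[-1].length > 0
        assert child_length(gens[-1].length, 0.5, 20.0) == 0.0


class TestPlantTotals:
    def test_zero_height(self):
        params = PlantParams()
        assert plant_volume(0.0, params) == 0.0
        assert plant_surface_area(0.0, params) == 0.0
        assert basal_cross_section_total(0.0, params) == 0.0
        assert twig_count(0.0, params) == 0

    def test_hand_assembled_volume_and_area(self):
        """Two-generation plant matches the sum of closed-form segments."""
        params = PlantParams()
        stem = Segment(20.0, 0.15, 0.1)
        branch = Segment(10.0, 0.1, 0.1)
        assert plant_volume(20.0, params) == pytest.approx(
            frustum_volume(stem) + 2 * frustum_volume(branch), rel=1e-14
        )
        assert plant_surface_area(20.0, params) == pytest.approx(
            frustum_lateral_area(stem) + 2 * frustum_lateral_area(branch), rel=1e-14
        )

    def test_brute_force_three_generation_oracle(self):
        """Explicit hand enumeration of all segments at h=40."""
        params = PlantParams()
        # generations: 40 (x1), 20 (x2), 10 (x4); radii 0.3, 0.15, 0.1
        segs = [(1, Segment(40.0, 0.3, 0.1)),
                (2, Segment(20.0, 0.15, 0.1)),
                (4, Segment(10.0, 0.1, 0.1))]
        vol = sum(c * frustum_volume(s) for c, s in segs)
        area = sum(c * frustum_lateral_area(s) for c, s in segs)
        assert plant_volume(40.0, params) == pytest.approx(vol, rel=1e-12)
        assert plant_surface_area(40.0, params) == pytest.approx(area, rel=1e-12)

    @given(st.floats(0.01, 500.0), st.sampled_from([2, 3, 5, 7]))
    @settings(max_examples=60)
    def test_volume_is_n_fold(self, h, n):
        """Stems are independent copies: V(h; n) = n V(h; 1) exactly."""
        assert plant_volume(h, PlantParams(n=n)) == n * plant_volume(h, PlantParams(n=1))

    @given(st.floats(0.1, 400.0), st.floats(0.1, 400.0))
    @settings(max_examples=60)
    def test_strict_monotonicity(self, h1, h2):
        lo, hi = min(h1, h2), max(h1, h2)
        if hi <= lo:
            hi = lo * 1.001
        params = PlantParams()
        assert plant_volume(hi, params) > plant_volume(lo, params)
        assert plant_surface_area(hi, params) > plant_surface_area(lo, params)

    @pytest.mark.parametrize("joint", [40.0 / 3.0, 20.0, 80.0 / 3.0, 40.0])
    def test_continuity_across_ramp_joints(self, joint):
        """V and S are continuous where generations are born or ramps end."""
        params = PlantParams()
        eps = 1e-9
        for fn in (plant_volume, plant_surface_area):
            lo, hi = fn(joint - eps, params), fn(joint + eps, params)
            assert abs(hi - lo) / max(hi, 1e-300) < 1e-9

    def test_twig_count_values(self):
        assert twig_count(10.0, PlantParams(n=3)) == 3
        assert twig_count(80.0, PlantParams(n=1)) == 8
        assert twig_count(80.0, PlantParams(n=5)) == 40

    def test_twig_count_monotone_with_factor_a_jumps(self):
        params = PlantParams()
        prev = None
        counts = []
        for h in [1, 5, 13, 14, 20, 26, 27, 40, 53, 54, 80, 110, 160]:
            c = twig_count(float(h), params)
            if prev is not None:
                assert c >= prev
            prev = c
            counts.append(c)
        distinct = sorted(set(counts))
        assert all(b // a_ == 2 and b % a_ == 0 for a_, b in zip(distinct, distinct[1:]))

    def test_basal_cross_section_hand_value(self):
        assert basal_cross_section_total(20.0, PlantParams()) == pytest.approx(
            math.pi * 0.15**2, rel=1e-14
        )

    def test_sprout_area_basal_fraction(self):
        """Sprouting area covers only the basal fraction of each stem."""
        params = PlantParams(n=3)
        full_stem = 3 * frustum_lateral_area(Segment(40.0, 0.3, 0.1))
        quarter = sprout_area(40.0, params, stem_fraction=0.25)
        assert 0 < quarter < full_stem
        assert sprout_area(40.0, params, stem_fraction=1.0) == pytest.approx(
            full_stem, rel=1e-12
        )
        with pytest.raises(ValueError):
            sprout_area(40.0, params, stem_fraction=1.5)


class TestNiklasSpatzMode:
    def test_forward_value(self):
        ns = NiklasSpatzParams(k5=1.0, k6=0.0)
        assert stem_length_from_diameter_ns(8.0, ns) == pytest.approx(4.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=50)
    def test_round_trip(self, diameter):
        ns = NiklasSpatzParams(k5=30.0, k6=5.0)
        length = stem_length_from_diameter_ns(diameter, ns)
        assert diameter_from_stem_length_ns(length, ns) == pytest.approx(
            diameter, rel=1e-10
        )

    def test_mode_requires_constants(self):
        with pytest.raises(ValueError):
            PlantParams(radius_mode="niklas_spatz")

    def test_totals_finite_in_ns_mode(self):
        params = PlantParams(radius_mode="niklas_spatz", ns=NiklasSpatzParams(30.0, 5.0))
        v = plant_volume(100.0, params)
        assert v > 0 and math.isfinite(v)
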
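"""Density targets: count conservation, superposition, clipping semantics."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sndm.synth import ColonyAnnotation, DishGeometry
from sndm.targets import (DensityTarget, KernelSpec, centers_from_bboxes,
                          count_from_map, loss_view, render_density_target)


def _kernel(sigma=1.0):
    return KernelSpec(sigma_blur=sigma, adaptive=False)


class TestCentersFromBboxes:
    @pytest.fixture
    def geometry(self):
        return DishGeometry(40, 40, 20.0, 20.0, 18.0)

    def test_midpoint_same_resolution(self, geometry):
        ann = ColonyAnnotation("x", geometry, [(10, 10, 20, 20)])
        assert centers_from_bboxes(ann, (40, 40)) == [(15.0, 15.0)]

    def test_empty_annotation(self, geometry):
        ann = ColonyAnnotation("x", geometry, [])
        assert centers_from_bboxes(ann, (40, 40)) == []

    def test_half_resolution_rescaling(self):
        g = DishGeometry(40, 40, 20.0, 20.0, 19.9)
        ann = ColonyAnnotation("x", g, [])
        ann.boxes = [(0, 0, 5, 8)]     # corner box; bypass dish-circle check
        (row, col), = centers_from_bboxes(ann, (20, 20))
        assert (row, col) == (2.0, 1.25)

    def test_box_outside_image_rejected(self, geometry):
        ann = ColonyAnnotation("x", geometry, [(10, 10, 20, 20)])
        ann.boxes = [(10, 10, 50, 20)]     # bypass constructor validation
        with pytest.raises(ValueError, match="outside image"):
            centers_from_bboxes(ann, (40, 40))


class TestRenderDensityTarget:
    def test_zero_centers_zero_map(self):
        t = render_density_target([], (32, 32), _kernel())
        assert t.count == 0.0
        assert np.all(t.map == 0)

    def test_single_center_unit_mass(self):
        t = render_density_target([(16.0, 16.0)], (32, 32), _kernel(2.0))
        assert t.map.sum() == pytest.approx(1.0, abs=1e-6)

    def test_edge_center_renormalised_to_unit_mass(self):
        # one pixel from the edge: a large part of the kernel is clipped away
        sigma = 2.0
        t = render_density_target([(1.0, 16.0)], (32, 32), _kernel(sigma))
        assert t.map.sum() == pytest.approx(1.0, abs=1e-6)
        # oracle: direct summation of the truncated kernel shows the clipping
        rr, cc = np.mgrid[-8:33, 8:25].astype(float)
        d2 = (rr - 1.0) ** 2 + (cc - 16.0) ** 2
        k = np.exp(-d2 / (2 * sigma * sigma))
        k[d2 > (4 * sigma) ** 2] = 0
        inside = k[(rr >= 0) & (rr < 32)].sum() / k.sum()
        assert inside < 0.95          # clipping really removed mass
        peak_expected = k.max() / k[(rr >= 0) & (rr < 32)].sum()
        assert t.map.max() == pytest.approx(peak_expected, rel=1e-9)

    def test_center_outside_map_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_density_target([(40.0, 16.0)], (32, 32), _kernel())

    def test_superposition(self):
        a = [(10.0, 10.0), (20.0, 15.0)]
        b = [(5.5, 25.0)]
        k = _kernel(1.5)
        combined = render_density_target(a + b, (32, 32), k).map
        separate = (render_density_target(a, (32, 32), k).map
                    + render_density_target(b, (32, 32), k).map)
        assert np.allclose(combined, separate, atol=1e-12)

    def test_integer_shift_equivariance_away_from_edges(self):
        k = _kernel(1.0)
        base = render_density_target([(12.0, 12.0)], (32, 32), k).map
        shifted = render_density_target([(15.0, 17.0)], (32, 32), k).map
        assert np.array_equal(np.roll(base, (3, 5), axis=(0, 1)), shifted)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.5, 30.5), st.floats(0.5, 30.5)),
                    min_size=0, max_size=25),
           st.floats(0.4, 3.0))
    def test_conservation_property(self, centers, sigma):
        t = render_density_target(list(centers), (31, 31), _kernel(sigma))
        assert abs(t.map.sum() - len(centers)) < 1e-5 * max(1, len(centers))


class TestCountFromMap:
    def test_zero_map(self):
        assert count_from_map(np.zeros((8, 8))) == 0.0

    def test_uniform_map_sums_to_one(self):
        assert count_from_map(np.full((10, 20), 1 / 200)) == pytest.approx(1.0)

    def test_sixteen_centers_conserved(self, rng):
        centers = [(float(r), float(c)) for r, c in
                   rng.uniform(2, 30, size=(16, 2))]
        t = render_density_target(centers, (32, 32), _kernel(1.0))
        assert count_from_map(t.map) == pytest.approx(16.0, abs=1e-5)

    def test_negative_entries_rejected(self):
        m = np.zeros((4, 4))
        m[0, 0] = -0.1
        with pytest.raises(ValueError):
            count_from_map(m)


class TestKernelSpec:
    def test_sigma_floor_enforced(self):
        with pytest.raises(ValueError):
            KernelSpec(sigma_blur=0.1, adaptive=False)

    def test_truncation_below_3_sigma_rejected(self):
        spec = KernelSpec(sigma_blur=2.0, adaptive=False, truncation_radius=4.0)
        with pytest.raises(ValueError, match="3\\*sigma"):
            spec.resolve_truncation(2.0)

    def test_adaptive_sigma_scales_with_box_side(self):
        g = DishGeometry(100, 100, 50.0, 50.0, 45.0)
        ann = ColonyAnnotation("x", g, [(40, 40, 60, 60)])   # side 20
        spec = KernelSpec(adaptive=True)
        assert spec.resolve_sigma(ann, scale=1.0) == pytest.approx(5.0)
        assert spec.resolve_sigma(ann, scale=0.5) == pytest.approx(2.5)
        # floor applies for tiny boxes
        tiny = ColonyAnnotation("x", g, [(49, 49, 50, 50)])
        assert spec.resolve_sigma(tiny, scale=1.0) == pytest.approx(0.4)


class TestLossView:
    def test_in_range_map_only_floor_changes(self):
        t = render_density_target([(16.0, 16.0)], (32, 32), _kernel(2.0))
        assert t.map.max() < 0.05
        v = loss_view(t, eps=1e-6)
        changed = v != t.map
        assert np.all(t.map[changed] < 1e-6)

    def test_overlapping_colonies_clip_and_warn(self, caplog):
        t = render_density_target([(16.0, 16.0), (16.0, 16.0)], (32, 32),
                                  _kernel(0.4))
        # oracle: two superposed unit-mass kernels exceed 1 at the shared peak
        assert t.map.max() > 1.0
        with caplog.at_level(logging.WARNING, logger="sndm.targets"):
            v = loss_view(t, eps=1e-6)
        assert v.max() == pytest.approx(1.0 - 1e-6)
        assert any("clipped" in r.message for r in caplog.records)
        # counting still uses the unclipped map
        assert t.map.sum() == pytest.approx(2.0, abs=1e-6)

    def test_invalid_eps_rejected(self):
        t = render_density_target([], (8, 8), _kernel())
        with pytest.raises(ValueError):
            loss_view(t, eps=0.6)


class TestDensityTargetInvariants:
    def test_sum_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pixel sum"):
            DensityTarget(map=np.full((4, 4), 0.1), count=5.0)

    def test_negative_entries_rejected(self):
        m = np.zeros((4, 4))
        m[1, 1] = -0.5
        with pytest.raises(ValueError, match="non-negative"):
            DensityTarget(map=m, count=-0.5)
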
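"""Universal-coordinate construction: u -> slice, v -> boundary point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneecdi import (
    SurfaceCoordinate,
    UnmeasurableLocationError,
    ValidationError,
    arclength_parameterize,
    mirror_contour_set,
    resolve_location,
    slice_for_u,
)
from kneecdi.geometry import check_orientation
from kneecdi.phantom import PhantomSpec, generate_phantom

from conftest import stack_of, straight_slice


class _Stub:
    def __init__(self, medial, lateral):
        self.medial_slice = medial
        self.lateral_slice = lateral


def brute_force_slice(medial, lateral, u):
    """Oracle: nearest slice to the continuous target; ties -> farther
    from the medial end."""
    target = medial + u * (lateral - medial)
    idxs = range(min(medial, lateral), max(medial, lateral) + 1)
    best = min(idxs, key=lambda i: (abs(i - target), -abs(i - medial)))
    return best


class TestSliceForU:
    @pytest.mark.parametrize(
        "medial,lateral,u,expected",
        [
            (10, 60, 0.5, 35),
            (10, 60, 0.0, 10),
            (10, 60, 1.0, 60),
            (10, 60, 0.25, 23),  # tie 22.5 -> farther from medial
            (60, 10, 0.25, 47),  # mirror image of the tie above
        ],
    )
    def test_examples(self, medial, lateral, u, expected):
        assert slice_for_u(_Stub(medial, lateral), u) == expected

    def test_out_of_range_u(self):
        with pytest.raises(ValidationError):
            slice_for_u(_Stub(0, 4), 1.2)

    @given(
        medial=st.integers(0, 30),
        span=st.integers(1, 40),
        reverse=st.booleans(),
        u=st.floats(0, 1, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force(self, medial, span, reverse, u):
        lateral = medial + (-span if reverse and medial >= span else span)
        assert slice_for_u(_Stub(medial, lateral), u) == brute_force_slice(
            medial, lateral, u
        )

    @pytest.mark.parametrize("medial,lateral", [(0, 4), (7, 3), (2, 12)])
    def test_surjective_onto_slice_range(self, medial, lateral):
        stub = _Stub(medial, lateral)
        hit = {slice_for_u(stub, u) for u in np.linspace(0, 1, 2001)}
        lo, hi = min(medial, lateral), max(medial, lateral)
        assert hit == set(range(lo, hi + 1))

    def test_mirror_symmetry_including_ties(self):
        # reflecting the stack must reflect every slice choice, ties included
        medial, lateral = 10, 60
        for u in np.linspace(0, 1, 501):
            fwd = slice_for_u(_Stub(medial, lateral), u)
            rev = slice_for_u(_Stub(lateral, medial), u)
            assert fwd + rev == medial + lateral


class TestArcLength:
    def test_straight_segment(self):
        amap = arclength_parameterize([(0, 0), (10, 0)])
        assert amap.length == pytest.approx(10.0)
        assert amap(0.3) == pytest.approx([3.0, 0.0])

    def test_resampling_invariance_collinear(self):
        x = np.linspace(0, 10, 100)
        amap = arclength_parameterize(np.stack([x, np.zeros_like(x)], axis=1))
        for v in (0.0, 0.3, 0.77, 1.0):
            assert np.allclose(amap(v), [10 * v, 0.0], atol=1e-9)

    def test_quarter_circle_midpoint(self):
        theta = np.deg2rad(np.arange(0, 91))
        arc = 10 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        amap = arclength_parameterize(arc)
        mid = amap(0.5)
        analytic = 10 * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4)])
        assert np.linalg.norm(mid - analytic) < 0.02
        assert amap.length == pytest.approx(10 * np.pi / 2, rel=1e-3)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            arclength_parameterize([(1.0, 1.0), (1.0, 1.0)])

    def test_endpoints(self):
        amap = arclength_parameterize([(0, 0), (2, 0), (2, 5)])
        assert np.allclose(amap(0.0), [0, 0])
        assert np.allclose(amap(1.0), [2, 5])

    def test_project_inverts_mapping(self):
        theta = np.deg2rad(np.arange(0, 91))
        arc = 10 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        amap = arclength_parameterize(arc)
        for v in (0.1, 0.5, 0.9):
            assert amap.project(amap(v)) == pytest.approx(v, abs=1e-6)


class TestResolveLocation:
    def test_corner_locations(self):
        cs = stack_of(
            [straight_slice(0, "femur"), straight_slice(1, "femur")]
        )
        idx, pt = resolve_location(cs, SurfaceCoordinate(0, 0), "femur")
        assert idx == 0 and np.allclose(pt, [0, 0])
        idx, pt = resolve_location(cs, SurfaceCoordinate(1, 1), "femur")
        assert idx == 1 and np.allclose(pt, [30, 0])

    def test_missing_contour_signals_unmeasurable(self):
        cs = stack_of(
            [straight_slice(0, "femur"), straight_slice(2, "femur")],
            n_slices=3,
        )
        with pytest.raises(UnmeasurableLocationError) as err:
            resolve_location(cs, SurfaceCoordinate(0.5, 0.5), "femur", name="F5")
        assert err.value.knee_id == "toy"
        assert err.value.location == "F5"

    def test_cylindrical_condyle_grid_against_analytic(self):
        # 3x3 (u, v) grid on an analytic condyle arc: resolved points must
        # match the closed-form arc positions to 0.1 mm
        spec = PhantomSpec(points_per_contour=181)
        cs, _ = generate_phantom(spec)
        R, half = spec.femur_radius, spec.femur_halfangle
        center = np.array([40.0, 45.0])
        for u in (0.0, 0.5, 1.0):
            for v in (0.0, 0.5, 1.0):
                idx, pt = resolve_location(cs, SurfaceCoordinate(u, v), "femur")
                phi = -half + v * 2 * half
                analytic = center + R * np.array([np.sin(phi), -np.cos(phi)])
                assert np.linalg.norm(pt - analytic) < 0.1

    def test_invariant_to_slice_storage_order(self):
        slices = [straight_slice(i, "femur") for i in range(4)]
        cs1 = stack_of(list(slices))
        cs2 = stack_of(list(reversed(slices)))
        for u, v in [(0.0, 0.2), (0.6, 0.9), (1.0, 0.5)]:
            i1, p1 = resolve_location(cs1, SurfaceCoordinate(u, v), "femur")
            i2, p2 = resolve_location(cs2, SurfaceCoordinate(u, v), "femur")
            assert i1 == i2
            assert np.allclose(p1, p2, atol=1e-12)

    def test_curved_resampling_tolerance(self):
        theta = np.linspace(0, np.pi / 2, 91)
        arc_coarse = 10 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        theta_f = np.linspace(0, np.pi / 2, 721)
        arc_fine = 10 * np.stack([np.cos(theta_f), np.sin(theta_f)], axis=1)
        a1 = arclength_parameterize(arc_coarse)
        a2 = arclength_parameterize(arc_fine)
        for v in np.linspace(0, 1, 11):
            assert np.linalg.norm(a1(v) - a2(v)) < 0.05


class TestMirrorAndOrientation:
    def test_mirrored_knee_resolves_same_points(self):
        spec = PhantomSpec(side="right")
        cs, _ = generate_phantom(spec)
        mirrored = mirror_contour_set(cs)
        assert mirrored.side == "left"
        for u, v in [(0.0, 0.0), (0.25, 0.5), (0.5, 0.31), (1.0, 1.0)]:
            i1, p1 = resolve_location(cs, SurfaceCoordinate(u, v), "femur")
            i2, p2 = resolve_location(mirrored, SurfaceCoordinate(u, v), "femur")
            # physical slice identity: reflected index, identical point
            assert i2 == cs.medial_slice + cs.lateral_slice - i1 or i2 == i1
            assert np.allclose(p1, p2, atol=1e-12)

    def test_orientation_checker_flags_reversed_slice(self):
        slices = [straight_slice(i, "femur") for i in range(5)]
        slices[2] = straight_slice(2, "femur")
        slices[2].bone_boundary = slices[2].bone_boundary[::-1].copy()
        slices[2].cartilage_surface = slices[2].cartilage_surface[::-1].copy()
        cs = stack_of(slices)
        assert check_orientation(cs, "femur") == [2]
        assert check_orientation(cs, "tibia") == []
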
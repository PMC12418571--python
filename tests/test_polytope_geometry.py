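"""Geometry engine: half-space clipping, volumes, overlap, slab excess."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vvoqc import (
    ConvexPolytope,
    HalfSpace,
    clip_halfspace,
    make_cuboid,
    mc_overlap_oracle,
    overlap_fraction,
    params_to_transform,
    polytope_volume,
    slab_excess_volumes,
)
from vvoqc.polytope_geometry import cuboid_halfspaces


class TestMakeCuboid:
    @pytest.mark.parametrize(
        "dims, expected_volume",
        [((1, 1, 1), 1.0), ((3, 3, 3), 27.0), ((2, 2, 4), 16.0)],
    )
    def test_volume(self, dims, expected_volume):
        poly = make_cuboid((0, 0, 0), dims)
        assert len(poly.vertices) == 8
        assert polytope_volume(poly) == pytest.approx(expected_volume, abs=1e-12)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            make_cuboid((0, 0, 0), (1, 0, 1))

    def test_vertices_at_center_plus_minus_half_dims(self):
        poly = make_cuboid((1, 2, 3), (2, 4, 6))
        lo = poly.vertices.min(axis=0)
        hi = poly.vertices.max(axis=0)
        np.testing.assert_allclose(lo, [0, 0, 0])
        np.testing.assert_allclose(hi, [2, 4, 6])


class TestClipHalfspace:
    def test_plane_through_middle_halves_volume(self):
        cube = make_cuboid((0.5, 0.5, 0.5), (1, 1, 1))
        hs = HalfSpace(point=(0.5, 0, 0), normal=(-1, 0, 0))  # keep x <= 0.5
        clipped = clip_halfspace(cube, hs)
        assert polytope_volume(clipped) == pytest.approx(0.5, abs=1e-12)

    def test_halfspace_containing_polytope_is_identity(self):
        cube = make_cuboid((0, 0, 0), (2, 2, 2))
        hs = HalfSpace(point=(0, 0, -10), normal=(0, 0, 1))
        clipped = clip_halfspace(cube, hs)
        assert polytope_volume(clipped) == pytest.approx(8.0, abs=1e-12)

    def test_halfspace_excluding_polytope_gives_empty(self):
        cube = make_cuboid((0, 0, 0), (2, 2, 2))
        hs = HalfSpace(point=(0, 0, 10), normal=(0, 0, 1))
        clipped = clip_halfspace(cube, hs)
        assert clipped.is_empty
        assert polytope_volume(clipped) == 0.0

    def test_rotated_cube_clip_matches_monte_carlo(self, rng):
        """Clipping a rotated cube by an oblique plane agrees with point sampling."""
        T = params_to_transform([0.3, -0.2, 0.1, 0.2, -0.15, 0.1])
        cube = make_cuboid((0, 0, 0), (2, 2, 2))
        moved = ConvexPolytope(vertices=T.apply(cube.vertices), faces=[T.apply(f) for f in cube.faces])
        normal = np.array([1.0, 1.0, 0.5])
        normal /= np.linalg.norm(normal)
        hs = HalfSpace(point=(0.2, 0.0, 0.0), normal=normal)
        clipped_vol = polytope_volume(clip_halfspace(moved, hs))
        # MC oracle: sample uniformly in the cube, move, test side of plane
        n = 10**6
        pts = T.apply((rng.random((n, 3)) - 0.5) * 2.0)
        p = np.mean((pts - hs.point) @ hs.normal >= 0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(clipped_vol / 8.0 - p) < 3 * se


class TestPolytopeVolume:
    def test_unit_tetrahedron(self):
        tet = ConvexPolytope(vertices=[(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert polytope_volume(tet) == pytest.approx(1 / 6, abs=1e-12)

    @pytest.mark.parametrize(
        "vertices",
        [
            [],
            [(0, 0, 0)],
            [(0, 0, 0), (1, 0, 0)],
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)],  # planar
        ],
    )
    def test_degenerate_sets_have_zero_volume(self, vertices):
        poly = ConvexPolytope(vertices=np.asarray(vertices, dtype=float).reshape(-1, 3))
        assert polytope_volume(poly) == 0.0


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "shift, dim, expected",
        [
            (2.0, 4.0, 0.5),  # half a voxel moved out
            (1.0, 3.0, 2 / 3),  # 18/27 mm^3
            (1.0, 2.0, 0.5),
            (1.0, 1.0, 0.0),
        ],
    )
    def test_single_axis_shift_closed_form(self, shift, dim, expected):
        T = params_to_transform([shift, 0, 0, 0, 0, 0])
        got = overlap_fraction(T, (0, 65, 0), (dim, dim, dim))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identity_is_exactly_one(self):
        T = params_to_transform([0, 0, 0, 0, 0, 0])
        assert overlap_fraction(T, (12.0, -3.0, 65.0), (3, 3, 3)) == 1.0

    def test_translation_product_formula(self, rng):
        """Pure shift s: overlap = prod_i max(0, 1 - |s_i|/d_i)."""
        for _ in range(25):
            s = rng.uniform(-4, 4, 3)
            d = rng.uniform(0.5, 4.5, 3)
            T = params_to_transform([*s, 0, 0, 0])
            expected = np.prod(np.maximum(0.0, 1.0 - np.abs(s) / d))
            got = overlap_fraction(T, (5.0, -7.0, 2.0), tuple(d))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_rigid_symmetry_forward_equals_inverse(self, rng):
        """Volume preservation: overlap(T) == overlap(T^-1)."""
        for _ in range(100):
            p = np.concatenate([rng.uniform(-1.5, 1.5, 3), rng.uniform(-0.015, 0.015, 3)])
            T = params_to_transform(p)
            f = overlap_fraction(T, (0, 65, 0), (3, 3, 3))
            b = overlap_fraction(T.inverse(), (0, 65, 0), (3, 3, 3))
            assert abs(f - b) < 1e-9

    def test_quarter_turn_about_own_center_is_full_overlap(self):
        """A cube rotated 90 deg about its own axis coincides with itself."""
        T = params_to_transform([0, 0, 0, 0, 0, np.pi / 2])
        assert overlap_fraction(T, (0, 0, 0), (3, 3, 3)) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_shift_magnitude(self):
        shifts = np.linspace(0, 4, 17)
        vals = [
            overlap_fraction(params_to_transform([s, 0, 0, 0, 0, 0]), (0, 65, 0), (3, 3, 3))
            for s in shifts
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rotation_case_matches_monte_carlo(self):
        T = params_to_transform([0, 0, 0, 0, 0, 0.004])  # small yaw, ~0.26 mm at 65 mm
        c, dims = (0, 65, 0), (3, 3, 3)
        exact = overlap_fraction(T, c, dims)
        est = mc_overlap_oracle(T, c, dims, 10**6, seed=11)
        assert 0 < exact < 1
        assert abs(exact - est) < 0.002

    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
        st.floats(-0.02, 0.02), st.floats(-0.02, 0.02), st.floats(-0.02, 0.02),
    )
    def test_fraction_always_in_unit_interval(self, tx, ty, tz, rx, ry, rz):
        T = params_to_transform([tx, ty, tz, rx, ry, rz])
        f = overlap_fraction(T, (0, 65, 0), (3, 3, 3))
        assert 0.0 <= f <= 1.0


class TestSlabExcess:
    def test_pure_through_plane_shift(self):
        T = params_to_transform([0, 0, 1, 0, 0, 0])
        below, above = slab_excess_volumes(T, (0, 65, 0), (3, 3, 3), "z")
        assert below == pytest.approx(0.0, abs=1e-12)
        assert above == pytest.approx(9.0, abs=1e-9)

    def test_pure_in_plane_shift_has_no_z_excess(self):
        T = params_to_transform([1, 0, 0, 0, 0, 0])
        below, above = slab_excess_volumes(T, (0, 65, 0), (3, 3, 3), "z")
        assert below == above == pytest.approx(0.0, abs=1e-12)

    def test_mixed_shift_hand_geometry_and_conservation(self):
        """Shift (1,0,1) on a 3 mm voxel: overlap 12, above 9, in-plane 6."""
        T = params_to_transform([1, 0, 1, 0, 0, 0])
        c, dims = (0, 65, 0), (3, 3, 3)
        below, above = slab_excess_volumes(T, c, dims, "z")
        overlap_vol = 27.0 * overlap_fraction(T, c, dims)
        assert (below, above) == pytest.approx((0.0, 9.0), abs=1e-9)
        assert overlap_vol == pytest.approx(12.0, abs=1e-9)
        in_plane = 27.0 - overlap_vol - below - above
        assert in_plane == pytest.approx(6.0, abs=1e-9)

    def test_conservation_with_independent_slab_clip(self, rng):
        """overlap + out-of-plane + in-plane excess = voxel volume.

        The in-plane excess is computed independently by clipping the
        moved cuboid to the infinite slab (two inward planes) rather
        than as a remainder, so the identity is a real cross-check.
        """
        from vvoqc.polytope_geometry import _moved_cuboid

        c, dims = np.array([0.0, 65.0, 0.0]), (3.0, 3.0, 3.0)
        for _ in range(25):
            p = np.concatenate([rng.uniform(-1.5, 1.5, 3), rng.uniform(-0.01, 0.01, 3)])
            T = params_to_transform(p)
            overlap_vol = 27.0 * overlap_fraction(T, c, dims)
            below, above = slab_excess_volumes(T, c, dims, "z")
            slab = _moved_cuboid(T, c, dims)
            for sign in (-1.0, +1.0):
                point = c.copy()
                point[2] += sign * 1.5
                slab = clip_halfspace(slab, HalfSpace(point, (0, 0, -sign)))
            in_plane = polytope_volume(slab) - overlap_vol
            assert in_plane >= -1e-9
            assert overlap_vol + below + above + in_plane == pytest.approx(27.0, abs=1e-9)


class TestMonteCarloOracle:
    def test_identity_all_points_inside(self):
        T = params_to_transform([0, 0, 0, 0, 0, 0])
        assert mc_overlap_oracle(T, (0, 0, 65), (3, 3, 3), 10**4, seed=5) == 1.0

    def test_seed_reproducibility(self):
        T = params_to_transform([0.5, 0.2, -0.1, 0.003, 0, 0])
        a = mc_overlap_oracle(T, (0, 65, 0), (3, 3, 3), 10**5, seed=99)
        b = mc_overlap_oracle(T, (0, 65, 0), (3, 3, 3), 10**5, seed=99)
        assert a == b

    def test_known_half_overlap_within_three_se(self):
        T = params_to_transform([2, 0, 0, 0, 0, 0])
        est = mc_overlap_oracle(T, (0, 65, 0), (4, 4, 4), 10**6, seed=7)
        assert abs(est - 0.5) < 3 * np.sqrt(0.25 / 10**6)


def test_cuboid_halfspaces_intersection_reproduces_cuboid():
    cube = make_cuboid((1.0, -2.0, 0.5), (2, 3, 4))
    poly = make_cuboid((1.0, -2.0, 0.5), (20, 20, 20))
    for hs in cuboid_halfspaces((1.0, -2.0, 0.5), (2, 3, 4)):
        poly = clip_halfspace(poly, hs)
    assert polytope_volume(poly) == pytest.approx(polytope_volume(cube), abs=1e-9)
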
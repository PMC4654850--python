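"""Rotations, view transforms, the wedge coordinate system and
line/ellipsoid intersection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyespot.geometry import (
    EyeModel,
    ViewTransform,
    apply_view,
    euler_xyz_from_matrix,
    invert_view,
    line_ellipsoid_nearest,
    normalize_to_sphere,
    rotation_matrix,
    spherical_polar,
    wedge_arc,
    wedge_coordinates_both_axes,
    wedge_forward,
    wedge_fractions_both_axes,
    wedge_inverse,
)
from eyespot.geometry import _lines_ellipsoid_nearest

from helpers_oracles import arc_point_oracle

PHI0 = 127.0
SIN_PHI0 = np.sin(np.deg2rad(PHI0))
RIM_Z = -np.cos(np.deg2rad(PHI0))  # = cos(53 deg)


class TestRotationMatrix:
    def test_identity(self):
        assert np.allclose(rotation_matrix((0, 0, 0)), np.eye(3))

    def test_quarter_turn_about_z(self):
        assert np.allclose(rotation_matrix((0, 0, 90)) @ [1, 0, 0], [0, 1, 0],
                           atol=1e-12)

    def test_matches_explicit_factor_product(self):
        """Entrywise equality with the hand-multiplied Rx*Ry*Rz factors."""
        ax, ay, az = np.deg2rad([30.0, 40.0, 50.0])
        rx = np.array([[1, 0, 0],
                       [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                       [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        rz = np.array([[np.cos(az), -np.sin(az), 0],
                       [np.sin(az), np.cos(az), 0],
                       [0, 0, 1]])
        assert np.allclose(rotation_matrix((30, 40, 50)), rx @ ry @ rz, atol=1e-12)

    def test_orthogonal_unit_determinant(self, rng):
        for angles in rng.uniform(-360, 360, size=(1000, 3)):
            r = rotation_matrix(angles)
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(r) - 1.0) < 1e-9

    def test_euler_angles_round_trip(self, rng):
        for angles in rng.uniform(-170, 170, size=(200, 3)):
            r = rotation_matrix(angles)
            recovered = euler_xyz_from_matrix(r)
            assert np.allclose(rotation_matrix(recovered), r, atol=1e-9)


class TestViewTransform:
    def test_pure_translation(self):
        view = ViewTransform((0, 0, 0), (5, 0, 0))
        assert np.allclose(apply_view([1, 2, 3], view), [6, 2, 3])

    def test_round_trip_random(self, rng):
        view = ViewTransform(tuple(rng.uniform(-180, 180, 3)),
                             tuple(rng.uniform(-10, 10, 3)))
        pts = rng.normal(size=(100, 3))
        assert np.allclose(invert_view(apply_view(pts, view), view), pts, atol=1e-9)

    def test_rotation_matrix_validated_orthogonal(self):
        view = ViewTransform((12.0, -34.0, 56.0))
        r = view.matrix
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(r) - 1.0) < 1e-9


class TestWedgeForward:
    def test_first_pole_for_every_psi(self):
        """f=0 lands on the same rim pole regardless of plane tilt."""
        psis = np.linspace(-90, 90, 37)
        pts = wedge_forward(psis, 0.0, PHI0)
        expected = np.array([SIN_PHI0, 0.0, RIM_Z])
        assert np.allclose(pts, expected, atol=1e-9)
        spread = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1).max()
        assert spread < 1e-9

    def test_second_pole(self):
        pts = wedge_forward(np.linspace(-90, 90, 19), 1.0, PHI0)
        assert np.allclose(pts, [-SIN_PHI0, 0.0, RIM_Z], atol=1e-9)

    def test_deepest_point(self):
        assert np.allclose(wedge_forward(0.0, 0.5, PHI0), [0, 0, -1], atol=1e-12)

    def test_matches_circle_geometry_oracle(self, rng):
        """Independent plane/sphere-intersection construction, many samples."""
        for _ in range(300):
            psi = rng.uniform(-89.0, 89.0)
            f = rng.uniform(0.0, 1.0)
            phi0 = rng.uniform(95.0, 175.0)
            assert np.allclose(wedge_forward(psi, f, phi0),
                               arc_point_oracle(psi, f, phi0), atol=1e-10)

    def test_worked_example(self):
        """The printed example point, first checked against the oracle."""
        oracle = arc_point_oracle(30.0, 0.25, 127.0)
        point = wedge_forward(30.0, 0.25, 127.0)
        assert np.allclose(point, oracle, atol=1e-10)
        assert np.allclose(point, [0.839, 0.488, -0.243], atol=1e-3 + 1e-9)

    def test_output_on_unit_sphere(self, rng):
        pts = wedge_forward(rng.uniform(-90, 90, 500), rng.uniform(0, 1, 500), PHI0)
        assert np.allclose(np.linalg.norm(pts, axis=-1), 1.0, atol=1e-12)

    def test_phi0_domain_error(self):
        with pytest.raises(ValueError):
            wedge_forward(0.0, 0.5, 90.0)
        with pytest.raises(ValueError):
            wedge_forward(0.0, 0.5, 181.0)


class TestWedgeInverse:
    def test_deepest_point_is_midpoint(self):
        psi, f, degenerate = wedge_inverse(np.array([0.0, 0.0, -1.0]), PHI0)
        assert f == pytest.approx(0.5, abs=1e-12)
        assert psi == pytest.approx(0.0)
        assert not degenerate

    def test_worked_example_inverse(self):
        point = wedge_forward(30.0, 0.25, 127.0)
        psi, f, _ = wedge_inverse(point, 127.0)
        assert psi == pytest.approx(30.0, abs=1e-9)
        assert f == pytest.approx(0.250, abs=1e-9)

    def test_poles_flagged_degenerate(self):
        psi, f, degenerate = wedge_inverse(np.array([SIN_PHI0, 0.0, RIM_Z]), PHI0)
        assert degenerate and psi == 0.0 and f == 0.0
        psi, f, degenerate = wedge_inverse(np.array([-SIN_PHI0, 0.0, RIM_Z]), PHI0)
        assert degenerate and psi == 0.0 and f == 1.0

    def test_above_rim_rejected(self):
        with pytest.raises(ValueError, match="above the rim"):
            wedge_inverse(np.array([0.0, 0.0, 1.0]), PHI0)

    def test_round_trip_forward_then_inverse(self, rng):
        psi = rng.uniform(-89.9, 89.9, 10_000)
        f = rng.uniform(0.0, 1.0, 10_000)
        pts = wedge_forward(psi, f, PHI0)
        psi_r, f_r, _ = wedge_inverse(pts, PHI0)
        assert np.abs(f_r - f).max() < 1e-10
        interior = (f > 1e-6) & (f < 1 - 1e-6)
        assert np.abs(psi_r - psi)[interior].max() < 1e-8

    def test_round_trip_inverse_then_forward(self, rng):
        """Random points strictly below the rim map back to themselves."""
        z = rng.uniform(-1.0 + 1e-6, RIM_Z - 1e-6, 10_000)
        theta = rng.uniform(0, 2 * np.pi, 10_000)
        s = np.sqrt(1 - z ** 2)
        pts = np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=-1)
        psi, f, _ = wedge_inverse(pts, PHI0)
        back = wedge_forward(psi, f, PHI0)
        assert np.linalg.norm(back - pts, axis=-1).max() < 1e-8


class TestWedgeArc:
    @pytest.mark.parametrize("phi0", [91.0, 110.0, 127.0, 150.0, 179.0])
    def test_span_below_full_turn(self, phi0):
        for psi in np.linspace(-90, 90, 25):
            arc = wedge_arc(psi, phi0)
            assert 0 < arc.span < 2 * np.pi
            assert arc.alpha0 > 0
            assert 0 < arc.rho <= 1 + 1e-12


class TestBothAxes:
    def test_deepest_point_both_handedness(self):
        for hand in ("left", "right"):
            nt, dv = wedge_coordinates_both_axes([0.0, 0.0, -1.0], PHI0, hand)
            assert nt.f == pytest.approx(0.5, abs=1e-12)
            assert dv.f == pytest.approx(0.5, abs=1e-12)

    def test_nt_pole_sits_on_dv_midarc(self):
        nt, dv = wedge_coordinates_both_axes([SIN_PHI0, 0.0, RIM_Z], PHI0)
        assert nt.f == 0.0 and nt.degenerate
        assert dv.f == pytest.approx(0.5, abs=1e-9)

    def test_handedness_flips_dv_only(self, rng):
        z = rng.uniform(-1, RIM_Z - 1e-3, 200)
        theta = rng.uniform(0, 2 * np.pi, 200)
        s = np.sqrt(1 - z ** 2)
        pts = np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=-1)
        nt_l, dv_l = wedge_fractions_both_axes(pts, PHI0, "left")
        nt_r, dv_r = wedge_fractions_both_axes(pts, PHI0, "right")
        assert np.allclose(nt_l, nt_r)
        assert np.allclose(dv_l + dv_r, 1.0, atol=1e-12)


class TestNormalizeToSphere:
    def test_semi_axis_endpoint(self, ellipsoid_eye):
        rx = ellipsoid_eye.semi_axes[0]
        assert np.allclose(normalize_to_sphere([rx, 0, 0], ellipsoid_eye), [1, 0, 0])

    def test_diagonal_division(self, ellipsoid_eye):
        rx, ry, _ = ellipsoid_eye.semi_axes
        p = [rx / np.sqrt(2), ry / np.sqrt(2), 0.0]
        assert np.allclose(normalize_to_sphere(p, ellipsoid_eye),
                           [1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-12)

    def test_sphere_preserves_direction(self, rng, unit_sphere_eye):
        p = rng.normal(size=3)
        assert np.allclose(normalize_to_sphere(p, unit_sphere_eye),
                           p / np.linalg.norm(p), atol=1e-12)

    def test_origin_rejected(self, unit_sphere_eye):
        with pytest.raises(ValueError):
            normalize_to_sphere([0.0, 0.0, 0.0], unit_sphere_eye)


class TestSphericalPolar:
    def test_deepest_point_is_plot_centre(self):
        colat, _ = spherical_polar(np.array([0.0, 0.0, -1.0]))
        assert colat == pytest.approx(0.0, abs=1e-12)

    def test_equator(self):
        colat, azim = spherical_polar(np.array([1.0, 0.0, 0.0]))
        assert colat == pytest.approx(90.0, abs=1e-12)
        assert azim == pytest.approx(0.0, abs=1e-12)

    def test_rim_points_sit_at_127_degrees(self, rng):
        """With a 53-degree opening every rim point exports at colatitude 127."""
        theta = rng.uniform(0, 2 * np.pi, 100)
        rim = np.stack([SIN_PHI0 * np.cos(theta), SIN_PHI0 * np.sin(theta),
                        np.full(100, RIM_Z)], axis=-1)
        colat, _ = spherical_polar(rim)
        assert np.abs(colat - 127.0).max() < 1e-9


class TestLineEllipsoidNearest:
    def test_axis_line_picks_viewer_side(self, unit_sphere_eye):
        p = line_ellipsoid_nearest([0, 0, 2], [0, 0, -2], unit_sphere_eye, mode="exact")
        assert np.allclose(p, [0, 0, 1], atol=1e-12)
        p = line_ellipsoid_nearest([0, 0, 2], [0, 0, -2], unit_sphere_eye,
                                   n_samples=4001, mode="sampled")
        assert np.allclose(p, [0, 0, 1], atol=1e-3)

    def test_tangent_line(self, unit_sphere_eye):
        p = line_ellipsoid_nearest([-2, 1, 0], [2, 1, 0], unit_sphere_eye, mode="exact")
        assert np.allclose(p, [0, 1, 0], atol=1e-9)

    def test_degenerate_line_rejected(self, unit_sphere_eye):
        with pytest.raises(ValueError):
            line_ellipsoid_nearest([1, 1, 1], [1, 1, 1], unit_sphere_eye)

    def test_sampled_agrees_with_quadratic(self, rng, ellipsoid_eye):
        n = 500
        xy = rng.uniform(-1.0, 1.0, (n, 2))
        r_max = ellipsoid_eye.r_max
        q1 = np.column_stack([xy, np.full(n, r_max)])
        q2 = np.column_stack([xy, np.full(n, -r_max)])
        ps, _ = _lines_ellipsoid_nearest(q1, q2, ellipsoid_eye, 2000, "sampled")
        pe, ve = _lines_ellipsoid_nearest(q1, q2, ellipsoid_eye, mode="exact")
        hit = ve <= 1e-9
        assert hit.sum() > 300
        dist = np.linalg.norm(ps - pe, axis=1)
        assert dist[hit].max() <= 2.0 * (2.0 * r_max / 2000)

    def test_sampling_error_shrinks_with_n(self, rng, ellipsoid_eye):
        """Halving behaviour: doubling the sample count halves the error."""
        n = 300
        xy = rng.uniform(-0.9, 0.9, (n, 2))
        r_max = ellipsoid_eye.r_max
        q1 = np.column_stack([xy, np.full(n, r_max)])
        q2 = np.column_stack([xy, np.full(n, -r_max)])
        pe, ve = _lines_ellipsoid_nearest(q1, q2, ellipsoid_eye, mode="exact")
        hit = ve <= 1e-9
        med = []
        for ns in (500, 1000, 2000):
            ps, _ = _lines_ellipsoid_nearest(q1, q2, ellipsoid_eye, ns, "sampled")
            med.append(np.median(np.linalg.norm(ps - pe, axis=1)[hit]))
        assert med[0] > med[1] > med[2]
        assert med[0] / med[1] > 1.5
        assert med[1] / med[2] > 1.5


class TestEyeModel:
    def test_invariants(self):
        eye = EyeModel((1.0, 2.0, 3.0), 53.0)
        assert eye.r_max == 3.0
        assert eye.phi0_deg == 127.0
        with pytest.raises(ValueError):
            EyeModel((1.0, -2.0, 3.0))
        with pytest.raises(ValueError):
            EyeModel((1.0, 1.0, 1.0), 95.0)
        with pytest.raises(ValueError):
            EyeModel((1.0, 1.0, 1.0), 53.0, "middle")


@settings(max_examples=200, derandomize=True)
@given(psi=st.floats(-89.9, 89.9), f=st.floats(0.001, 0.999),
       phi0=st.floats(95.0, 175.0))
def test_wedge_round_trip_property(psi, f, phi0):
    """inverse(forward) is the identity across the whole parameter box."""
    p = wedge_forward(psi, f, phi0)
    psi_r, f_r, degenerate = wedge_inverse(p, phi0)
    assert not degenerate
    assert f_r == pytest.approx(f, abs=1e-9)
    assert psi_r == pytest.approx(psi, abs=1e-6)
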
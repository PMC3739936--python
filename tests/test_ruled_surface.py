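import numpy as np
import pytest

from helixgeom import (
    AnalyticRuledSpec,
    DegenerateGeometryError,
    RuledSurface,
    arctan_transform,
    build_ruled_surface,
    conical_curvature,
    distribution_parameter,
    fit_polynomial_curve,
    groove_area,
    make_ruled_fixture,
    striction_points,
    surface_profile_moving_average,
)
from helixgeom.ruled_surface import strip_area, striction_xyz_tsv

from conftest import quiet_trace, random_rotation


def straight_trace(length, n, direction=(1.0, 0, 0), offset=(0, 0, 0)):
    s = np.linspace(0, length, n)
    pts = np.outer(s, direction) + np.asarray(offset, float)
    return quiet_trace("s", range(1, n + 1), pts)


class TestBuild:
    def test_parallel_segments_share_one_direction(self):
        ca = fit_polynomial_curve(straight_trace(4, 10))
        cb = fit_polynomial_curve(straight_trace(4, 10, offset=(0, 1, 0)))
        rs = build_ruled_surface(ca, cb, 12)
        assert np.abs(rs.directions - np.array([0, 1.0, 0])).max() < 1e-8
        assert np.abs(np.linalg.norm(rs.directions, axis=1) - 1).max() < 1e-12

    def test_equal_arclength_spacing_on_straight_curve(self):
        ca = fit_polynomial_curve(straight_trace(6, 10))
        cb = fit_polynomial_curve(straight_trace(6, 10, offset=(0, 2, 0)))
        rs = build_ruled_surface(ca, cb, 7)
        gaps = np.linalg.norm(np.diff(rs.points_a, axis=0), axis=1)
        assert np.abs(gaps - 1.0).max() < 1e-9

    def test_coincident_points_rejected(self):
        a = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(DegenerateGeometryError):
            RuledSurface.from_rulings(a, a)


class TestStriction:
    def test_skew_unit_lines_foot_at_origin(self):
        # ruling 1 through origin along x, ruling 2 through (0,0,1) along y:
        # the common perpendicular is the z-axis, foot on ruling 1 = origin
        pa = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]], float)
        pb = np.array([[1, 0, 0], [0, 1, 1], [1, 0, 2], [0, 1, 3]], float)
        rs = striction_points(RuledSurface.from_rulings(pa, pb))
        assert np.abs(rs.striction_points[0]).max() < 1e-12

    def test_cylinder_all_torsal_no_striction(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("cylinder", n_rulings=50))
        rs = striction_points(fx.surface)
        assert rs.torsal_flags.all()
        assert np.isnan(rs.striction_points).all()

    def test_helicoid_striction_is_the_axis(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("helicoid", n_rulings=200))
        rs = striction_points(fx.surface)
        assert np.linalg.norm(rs.striction_points[:, :2], axis=1).max() < 1e-6

    def test_striction_tsv_export(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("helicoid", n_rulings=50))
        tsv = striction_xyz_tsv(fx.surface)
        assert tsv.splitlines()[0] == "position\tx_nm\ty_nm\tz_nm\ttorsal"
        assert len(tsv.splitlines()) == 50  # header + 49 pairs


class TestDistributionParameter:
    def test_helicoid_constant_b(self):
        fx = make_ruled_fixture(
            AnalyticRuledSpec("helicoid", n_rulings=200, parameters={"b": 0.5})
        )
        lam = distribution_parameter(fx.surface)
        assert np.abs(lam.values - 0.5).max() < 1e-4

    def test_cylinder_zero_by_torsal_convention(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("cylinder", n_rulings=60))
        lam = distribution_parameter(fx.surface)
        assert np.array_equal(lam.values, np.zeros(59))

    def test_generic_surface_matches_dense_oracle(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("offset-helix-pair", n_rulings=500))
        lam = distribution_parameter(fx.surface)
        rel = np.abs(lam.values - fx.expected_lambda) / np.abs(fx.expected_lambda)
        assert rel.max() < 0.005

    def test_sign_flips_under_reflection(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("helicoid", n_rulings=100))
        lam0 = distribution_parameter(fx.surface)
        mirror = np.array([1.0, 1.0, -1.0])
        rs_m = RuledSurface.from_rulings(
            fx.surface.points_a * mirror, fx.surface.points_b * mirror
        )
        lam_m = distribution_parameter(rs_m)
        assert np.abs(lam_m.values + lam0.values).max() < 1e-10

    def test_invariant_under_rigid_motion(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("offset-helix-pair", n_rulings=80))
        lam0 = distribution_parameter(fx.surface)
        rng = np.random.default_rng(5)
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.normal(size=3)
            rs = RuledSurface.from_rulings(
                fx.surface.points_a @ R.T + t, fx.surface.points_b @ R.T + t
            )
            assert np.abs(distribution_parameter(rs).values - lam0.values).max() < 1e-8


class TestConicalCurvature:
    def test_helicoid_conoidal_zero(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("helicoid", n_rulings=200))
        J = conical_curvature(fx.surface)
        assert np.nanmax(np.abs(J.values)) < 1e-6

    def test_cone_of_revolution_cot_alpha(self):
        alpha = np.pi / 4
        fx = make_ruled_fixture(
            AnalyticRuledSpec("cone", n_rulings=500, parameters={"half_angle": alpha})
        )
        J = conical_curvature(fx.surface)
        assert np.nanmax(np.abs(np.abs(J.values) - 1.0 / np.tan(alpha))) < 1e-4

    def test_reversing_traversal_negates_J(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("offset-helix-pair", n_rulings=80))
        J0 = conical_curvature(fx.surface).values
        rs_r = RuledSurface.from_rulings(
            fx.surface.points_a[::-1], fx.surface.points_b[::-1]
        )
        J_r = conical_curvature(rs_r).values
        assert np.allclose(J_r[::-1][1:-1], -J0[1:-1], atol=1e-9)

    def test_matches_dense_oracle_on_generic_surface(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("offset-helix-pair", n_rulings=500))
        J = conical_curvature(fx.surface).values
        rel = np.abs((J[1:-1] - fx.expected_J[1:-1]) / fx.expected_J[1:-1])
        assert np.nanmax(rel) < 0.01


class TestConvergence:
    def test_first_order_or_better_on_closed_forms(self):
        ns = [50, 100, 200, 400]
        errs_lam, errs_J = [], []
        for n in ns:
            f = make_ruled_fixture(
                AnalyticRuledSpec("helicoid", n_rulings=n, parameters={"b": 0.5})
            )
            errs_lam.append(np.abs(distribution_parameter(f.surface).values - 0.5).max())
            f = make_ruled_fixture(AnalyticRuledSpec("cone", n_rulings=n))
            errs_J.append(
                np.nanmax(np.abs(np.abs(conical_curvature(f.surface).values) - 1.0))
            )
        slope_lam = -np.polyfit(np.log(ns), np.log(errs_lam), 1)[0]
        slope_J = -np.polyfit(np.log(ns), np.log(errs_J), 1)[0]
        assert slope_lam >= 1.0
        assert slope_J >= 1.0


class TestArctanTransform:
    def test_maps_into_open_interval(self):
        fx = make_ruled_fixture(AnalyticRuledSpec("cone", n_rulings=50))
        J = conical_curvature(fx.surface)
        out = arctan_transform(J)
        assert out.descriptor == "conical_curvature_arctan"
        finite = out.values[~np.isnan(out.values)]
        assert np.all(np.abs(finite) < np.pi / 2)
        assert np.array_equal(out.positions, J.positions)

    def test_reference_values(self):
        from helixgeom.diffgeo import ParameterProfile

        prof = ParameterProfile("conical_curvature", [1, 2, 3, 4],
                                [0.0, 1.0, np.inf, -np.inf])
        out = arctan_transform(prof)
        assert out.values[0] == 0.0
        assert out.values[1] == pytest.approx(np.pi / 4)
        assert out.values[2] == pytest.approx(np.pi / 2)
        assert out.values[3] == pytest.approx(-np.pi / 2)

    def test_rejects_other_descriptors(self):
        from helixgeom.diffgeo import ParameterProfile

        with pytest.raises(ValueError):
            arctan_transform(ParameterProfile("curvature", [1], [0.1]))


class TestGrooveArea:
    def test_planar_strip_exact(self):
        a = np.column_stack([np.linspace(0, 4, 10), np.zeros(10), np.zeros(10)])
        b = a + np.array([0, 1.0, 0])
        area, n_tri = strip_area(a, b)
        assert area == pytest.approx(4.0, rel=1e-12)
        assert n_tri == 18

    def test_area_monotone_under_widening(self):
        a = np.column_stack([np.linspace(0, 4, 10), np.zeros(10), np.zeros(10)])
        areas = [strip_area(a, a + np.array([0, w, 0]))[0] for w in (0.5, 1.0, 2.0)]
        assert areas[0] < areas[1] < areas[2]

    def test_groove_area_parallel_traces_with_tail_exclusion(self):
        # residues 0.4 nm apart along x; 3 C-terminal residues excluded
        # leaves 7 nodes -> strip 2.4 x 1.0 nm
        ta = straight_trace(3.6, 10)
        tb = straight_trace(3.6, 10, offset=(0, 1.0, 0))
        ga = groove_area(fit_polynomial_curve(ta), fit_polynomial_curve(tb), ta, tb)
        assert ga.a_total == pytest.approx(2.4, rel=1e-9)
        assert ga.n_residues_used == 14
        assert ga.a_per_residue == pytest.approx(ga.a_total / 14, rel=1e-12)

    def test_per_residue_identity(self, realistic_pair):
        ta, tb = realistic_pair
        ga = groove_area(fit_polynomial_curve(ta), fit_polynomial_curve(tb), ta, tb)
        assert ga.a_per_residue * ga.n_residues_used == pytest.approx(
            ga.a_total, rel=1e-12
        )

    def test_too_short_after_exclusion(self):
        ta = straight_trace(2.0, 6)
        tb = straight_trace(2.0, 6, offset=(0, 1, 0))
        with pytest.raises(ValueError):
            groove_area(fit_polynomial_curve(ta), fit_polynomial_curve(tb), ta, tb,
                        tail_exclusion=3)


class TestSurfaceMovingAverage:
    def test_constant_profile_stays_constant(self):
        from helixgeom.diffgeo import ParameterProfile

        prof = ParameterProfile("distribution_parameter",
                                np.arange(1, 11), np.full(10, 0.7))
        out = surface_profile_moving_average(prof, window=4)
        assert np.allclose(out.values, 0.7)
        assert len(out.positions) == 7

    @pytest.mark.parametrize("m,expected", [(39, 36), (37, 34)])
    def test_position_counts(self, m, expected):
        from helixgeom.diffgeo import ParameterProfile

        prof = ParameterProfile("distribution_parameter",
                                np.arange(1, m + 1), np.random.default_rng(0).normal(size=m))
        out = surface_profile_moving_average(prof, window=4)
        assert len(out.positions) == expected

    def test_too_few_positions(self):
        from helixgeom.diffgeo import ParameterProfile

        prof = ParameterProfile("distribution_parameter", [1, 2, 3], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            surface_profile_moving_average(prof, window=4)
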
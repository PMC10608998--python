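import numpy as np
import pytest
from scipy.integrate import quad

from hyperflow import (ChannelGeometry, FluidProperties, StructuredGrid2D,
                       analytic_straight_profile, centerline_velocity,
                       duct_max_to_mean, duct_midplane_ratio, build_grid,
                       grid_refinement_study, midplane_velocity,
                       relative_error_percent, reynolds_number,
                       solve_depth_averaged_stokes, transverse_profile)
from .conftest import ML_PER_H, Q3


class TestReynolds:
    def test_no_flow(self, geom, fluid):
        assert reynolds_number(fluid, geom, 0.0) == 0.0

    def test_linear_in_flow_rate(self, geom, fluid):
        assert reynolds_number(fluid, geom, 2 * Q3) == pytest.approx(
            2 * reynolds_number(fluid, geom, Q3), rel=1e-12)

    def test_highest_study_flow_rate(self, geom, fluid):
        # rho Q / (2 h mu) at 0.265 mL/h
        assert reynolds_number(fluid, geom, Q3) == pytest.approx(0.1426, abs=2e-4)

    def test_invalid_inputs(self, geom, fluid):
        with pytest.raises(ValueError):
            reynolds_number(FluidProperties(rho=1000.0, mu=1e-3), geom, -1.0)
        with pytest.raises(ValueError):
            FluidProperties(rho=1000.0, mu=-1.0)


class TestStraightProfile:
    def test_symmetric(self):
        ub = analytic_straight_profile(406e-6, 60e-6, Q3)
        y = np.linspace(0, 200e-6, 7)
        assert np.allclose(ub(y), ub(-y), rtol=1e-14)

    def test_flux_normalization_quadrature(self):
        W, h = 406e-6, 60e-6
        ub = analytic_straight_profile(W, h, Q3)
        flux, _ = quad(lambda y: ub(y) * h, -W / 2, W / 2, limit=200)
        assert flux == pytest.approx(Q3, rel=1e-8)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            analytic_straight_profile(-1.0, 60e-6, Q3)


class TestDuctSeries:
    def test_square_section_peak_factor(self):
        assert duct_max_to_mean(1.0, 1.0) == pytest.approx(2.096, abs=1e-3)

    def test_wide_slot_limits(self):
        assert duct_max_to_mean(100.0, 1.0) == pytest.approx(1.5, abs=0.01)
        assert duct_midplane_ratio(100.0) == pytest.approx(1.5, abs=1e-3)

    def test_deep_slot_limit(self):
        # width much smaller than depth: plug-like depth profile
        assert duct_midplane_ratio(0.005) == pytest.approx(1.0, abs=0.01)

    def test_ratio_continuous_along_contraction(self, geom):
        g = build_grid(geom, 256, 16)
        m = (g.x >= 0.0) & (g.x <= geom.L_c - g.expansion_smoothing)
        r = duct_midplane_ratio(g.W[m] / g.h)
        jumps = np.abs(np.diff(r)) / r[:-1]
        assert np.max(jumps) < 0.01


class TestSolver:
    def test_matches_brinkman_closed_form(self, field_straight):
        g = field_straight.grid
        ub = analytic_straight_profile(406e-6, 60e-6, Q3)
        i = g.nx // 2
        err = np.abs(field_straight.u_bar[i] - ub(g.Y[i]))
        assert err.max() < 0.01 * ub(0.0)

    def test_flux_conservation_random_stations(self, field_mid, geom):
        rng = np.random.default_rng(42)
        stations = rng.uniform(geom.x_min + 20e-6, geom.x_max - 20e-6, 20)
        for x in stations:
            assert field_mid.flux_through_station(float(x)) == pytest.approx(
                Q3, rel=5e-3)

    def test_no_slip_on_side_walls(self, field_mid):
        # the inlet station carries the imposed uniform profile, whose corner
        # values are not subject to the wall condition; every other station is
        umax = np.abs(field_mid.u_bar).max()
        wall_tangential = np.abs(field_mid.u_bar[1:, [0, -1]])
        assert wall_tangential.max() < 1e-6 * umax

    def test_mirror_symmetry(self, field_mid):
        umax = np.abs(field_mid.u_bar).max()
        assert np.abs(field_mid.u_bar - field_mid.u_bar[:, ::-1]).max() < 1e-5 * umax
        assert np.abs(field_mid.v_bar + field_mid.v_bar[:, ::-1]).max() < 1e-5 * umax

    def test_linearity_in_flow_rate(self, geom, fluid):
        grid = build_grid(geom, 64, 16)
        f1 = solve_depth_averaged_stokes(grid, fluid, Q3)
        f2 = solve_depth_averaged_stokes(grid, fluid, 2 * Q3)
        assert np.allclose(f2.u_bar, 2 * f1.u_bar,
                           rtol=1e-6, atol=1e-6 * np.abs(f1.u_bar).max())

    def test_creeping_flow_reversibility(self, fluid):
        grid = StructuredGrid2D.straight(W=406e-6, h=60e-6, length=500e-6,
                                         nx=16, ny=16)
        f_fwd = solve_depth_averaged_stokes(grid, fluid, Q3)
        f_rev = solve_depth_averaged_stokes(grid, fluid, -Q3)
        assert np.allclose(f_rev.u_bar, -f_fwd.u_bar,
                           atol=1e-9 * np.abs(f_fwd.u_bar).max())

    def test_low_re_warning(self, geom, fluid):
        grid = build_grid(geom, 32, 8)
        with pytest.warns(UserWarning, match="creeping-flow"):
            solve_depth_averaged_stokes(grid, fluid, 20 * Q3)


class TestMidplaneField:
    def test_centerline_monotone_in_contraction(self, field_mid, geom):
        # up to where the regularized expansion begins
        # the expansion influences the field upstream over a couple of
        # Brinkman screening lengths (h / sqrt(12) ~ 17 um); stop short of it
        delta = field_mid.grid.expansion_smoothing
        xs = np.linspace(5e-6, geom.L_c - delta - 30e-6, 60)
        u = centerline_velocity(field_mid, xs)
        assert np.all(np.diff(u) > 0.0)
        assert centerline_velocity(field_mid, [-5e-6])[0] < u[-1]

    def test_centerline_linearity(self, field_mid, geom):
        xs = np.linspace(0.0, 500e-6, 120)
        u = centerline_velocity(field_mid, xs)
        slope, icpt = np.polyfit(xs, u, 1)
        resid = u - (slope * xs + icpt)
        r2 = 1.0 - np.sum(resid ** 2) / np.sum((u - u.mean()) ** 2)
        assert r2 > 0.99

    def test_velocity_drops_after_expansion(self, field_mid, geom):
        xs = np.linspace(geom.L_c + 30e-6, geom.x_max - 100e-6, 40)
        u = centerline_velocity(field_mid, xs)
        assert np.all(np.diff(u) < 0.0)
        u_up = centerline_velocity(field_mid, [-400e-6])[0]
        # decays toward the straight-channel value (within 5% by the outlet)
        assert u[-1] == pytest.approx(u_up, rel=0.05)
        assert u[0] > 3 * u_up

    def test_transverse_profile_symmetric_peaked(self, field_mid):
        ys = np.linspace(-150e-6, 150e-6, 31)
        prof = transverse_profile(field_mid, -300e-6, ys)
        assert np.allclose(prof, prof[::-1], rtol=1e-4)
        assert np.argmax(prof) == 15

    def test_upstream_profile_matches_closed_form(self, field_mid):
        ys = np.linspace(-180e-6, 180e-6, 25)
        prof = transverse_profile(field_mid, -350e-6, ys)
        ub = analytic_straight_profile(406e-6, 60e-6, Q3)
        r = duct_midplane_ratio(406.0 / 60.0)
        assert np.max(np.abs(prof - r * ub(ys))) < 0.02 * (r * ub(0.0))

    def test_centerline_value_grows_toward_contraction(self, field_mid):
        stations = [-400e-6, -200e-6, 0.0, 200e-6, 400e-6]
        u0 = [transverse_profile(field_mid, x, [0.0])[0] for x in stations]
        assert np.all(np.diff(u0) > 0.0)

    def test_sampling_outside_domain_raises(self, field_mid, geom):
        with pytest.raises(ValueError):
            midplane_velocity(field_mid, geom.x_max + 1e-5, 0.0)
        with pytest.raises(ValueError):
            midplane_velocity(field_mid, -400e-6, 300e-6)

    def test_wide_slot_conversion_limit(self):
        assert duct_midplane_ratio(50.0) == pytest.approx(1.5, abs=2e-3)


class TestRefinementStudy:
    def test_ladder_errors(self, geom, fluid):
        df = grid_refinement_study(geom, fluid, Q3,
                                   [(48, 16), (96, 32), (192, 64)])
        assert df["error_pct"].iloc[-1] == 0.0
        # errors shrink (non-strictly) with refinement beyond the coarsest
        errs = df["error_pct"].to_numpy()
        assert errs[1] <= errs[0] + 1e-12

    def test_requires_two_resolutions(self, geom, fluid):
        with pytest.raises(ValueError):
            grid_refinement_study(geom, fluid, Q3, [(48, 16)])

    def test_mesh_study_error_formula(self):
        # the published 4-mesh study numbers: coarse mesh vs reference mesh
        assert relative_error_percent(145.51, 149.74) == pytest.approx(2.82, abs=5e-3)
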
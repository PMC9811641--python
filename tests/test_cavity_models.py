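"""Cavity-expansion forward models: crater law, slice ODE, droplet train."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cavibridge import cavity_models as cm
from cavibridge.materials import JetSpec, Material


class TestFrontPosition:
    def test_linear_growth(self):
        assert cm.cavity_front_position(10.0, 0.0) == 0.0
        assert cm.cavity_front_position(10.0, 1e-3) == pytest.approx(10e-3)
        assert cm.cavity_front_position(10.0, 2e-3) == pytest.approx(
            2 * cm.cavity_front_position(10.0, 1e-3)
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cm.cavity_front_position(10.0, -1e-3)


class TestInertialProfile:
    def test_zero_at_apex_and_at_t0(self, jet):
        u_c = 10.0
        t = 1e-4
        assert cm.inertial_profile(u_c * t, t, jet, u_c) == 0.0
        assert np.all(cm.inertial_profile(np.linspace(0, 1e-3, 50), 0.0, jet, u_c) == 0)

    def test_square_root_growth(self, jet):
        r1 = cm.inertial_profile(0.0, 1e-4, jet, 10.0)
        r4 = cm.inertial_profile(0.0, 4e-4, jet, 10.0)
        assert r4 == pytest.approx(2.0 * r1, rel=1e-12)

    @given(t=st.floats(1e-6, 1e-3), u_c=st.floats(1.0, 30.0))
    def test_causality_and_nonnegativity(self, t, u_c):
        jet = JetSpec(1000.0, 1e-4, 20.0)
        x = np.linspace(0, 2 * u_c * t + 1e-4, 64)
        r = cm.inertial_profile(x, t, jet, u_c)
        assert np.all(r >= 0)
        assert np.all(r[x > u_c * t] == 0)

    def test_profile_squared_affine_in_time(self, jet):
        x = 5e-4
        u_c = 10.0
        t0 = x / u_c
        ts = t0 + np.array([1e-5, 2e-5, 3e-5])
        r2 = np.array([cm.inertial_profile(x, t, jet, u_c) for t in ts]) ** 2
        diffs = np.diff(r2)
        assert diffs[0] == pytest.approx(diffs[1], rel=1e-9)


class TestRayleigh2D:
    def test_equilibrium_without_driving(self):
        t = np.linspace(0, 1e-3, 100)
        r = cm.rayleigh2d_integrate(lambda t: 0.0, 1e-4, 0.0, t, rho=998.0)
        assert np.allclose(r, 1e-4, rtol=1e-9)

    def test_impulsive_driving_gives_sqrt_asymptote(self):
        t = np.linspace(0, 1e-3, 2000)
        r = cm.rayleigh2d_integrate(
            lambda tt: 1e6 if tt < 1e-6 else 0.0, 1e-6, 0.0, t, rho=998.0
        )
        sel = t > 1e-4
        exponent = np.polyfit(np.log(t[sel]), np.log(r[sel]), 1)[0]
        assert exponent == pytest.approx(0.50, abs=0.02)

    def test_tolerance_refinement_converges(self):
        t = np.linspace(1e-7, 5e-4, 200)
        args = (lambda tt: 1e5 if tt < 5e-6 else 0.0, 1e-6, 0.0, t)
        coarse = cm.rayleigh2d_integrate(*args, rho=998.0, rtol=1e-8, atol=1e-12)
        fine = cm.rayleigh2d_integrate(*args, rho=998.0, rtol=1e-10, atol=1e-14)
        rel = np.abs(coarse[-1] - fine[-1]) / fine[-1]
        assert rel < 1e-6


class TestViscousDropCavity:
    def test_high_reynolds_matches_inviscid(self, jet):
        train = cm.train_from_jet(jet)
        t = np.linspace(0, 3 * train.period, 300)
        nearly_inviscid = Material("ideal", 1000.0, 1e-9, 0.072)
        r_v = cm.viscous_drop_cavity(
            train, nearly_inviscid, t, include_surface_tension=False
        )
        # independent inviscid reference: pure momentum feed then free coast
        c_p = cm.drive_pressure_coefficient(train.f, 1.0)
        p0 = c_p * 1000.0 * train.U_d**2
        t_feed = 4 * train.r_d / train.U_d
        r_ref = cm.rayleigh2d_integrate(
            lambda tt: p0 if tt <= t_feed else 0.0,
            cm.EPS_INIT * train.r_d, 0.0, t, rho=1000.0,
        )
        sel = t > t_feed
        assert np.max(np.abs(r_v[sel] - r_ref[sel]) / r_ref[sel]) < 0.01

    def test_viscosity_never_increases_max_radius(self, jet):
        train = cm.train_from_jet(jet)
        t = np.linspace(0, 5 * train.period, 200)
        maxima = []
        for mu in (1e-4, 1e-3, 1e-2, 1e-1):
            target = Material("m", 1000.0, mu, 0.072)
            maxima.append(
                cm.viscous_drop_cavity(
                    train, target, t, include_surface_tension=False
                ).max()
            )
        assert all(b <= a * (1 + 1e-9) for a, b in zip(maxima, maxima[1:]))

    def test_zero_impact_speed_no_growth(self, water):
        train = cm.DropletTrainSpec(
            r_d=5e-5, U_d=1e-30, f=0.5, h_cyl=2e-4, r_cyl=5e-5 / math.sqrt(3.0)
        )
        t = np.linspace(0, 1e-4, 50)
        r = cm.viscous_drop_cavity(train, water, t)
        assert r.max() <= cm.EPS_INIT * train.r_d * 1.01


class TestDropletTrain:
    def test_printed_geometry_example(self):
        jet = JetSpec(1000.0, 100e-6, 20.0)
        train = cm.train_from_jet(jet, f=0.5)
        assert train.r_cyl == pytest.approx(50e-6)
        assert train.r_d == pytest.approx(86.6e-6, rel=1e-3)
        assert train.h_cyl == pytest.approx(346.4e-6, rel=1e-3)

    @given(f=st.floats(0.05, 0.5))
    def test_volume_flux_equivalence(self, f):
        jet = JetSpec(1000.0, 100e-6, 20.0)
        train = cm.train_from_jet(jet, f=f)
        cyl_flux = math.pi * train.r_cyl**2 * train.U_d
        assert train.volume_flux == pytest.approx(cyl_flux, rel=1e-12)

    @given(f=st.floats(0.05, 0.5))
    def test_cavity_velocity_round_trip(self, f):
        jet = JetSpec(1000.0, 100e-6, 20.0)
        train = cm.train_from_jet(jet, f=f)
        u_c = cm.train_cavity_velocity(train.U_d, f)
        assert u_c == pytest.approx(0.5 * jet.U_0, rel=1e-9)

    def test_velocity_linear_in_drop_speed(self):
        assert cm.train_cavity_velocity(0.0, 0.5) == 0.0
        assert cm.train_cavity_velocity(20.0, 0.3) == pytest.approx(
            2 * cm.train_cavity_velocity(10.0, 0.3)
        )

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            cm.DropletTrainSpec(r_d=1e-4, U_d=10.0, f=0.5, h_cyl=1e-4, r_cyl=5e-5)


class TestSuperposedTrain:
    def test_single_drop_degenerates_to_slice_solution(self, water, jet):
        train = cm.train_from_jet(jet)
        t = 0.8 * train.period  # only the first drop has landed
        x, r = cm.superposed_train_profile(train, water, t, n_drops=1)
        tau = np.linspace(0, max(t, train.period), 512)
        r_single = cm.viscous_drop_cavity(train, water, tau)
        expected = np.interp(t, tau, r_single)
        band = x < 2 * train.r_d
        inside = r[band & (x <= cm.train_cavity_velocity(train.U_d, train.f) * t)]
        assert inside.max() == pytest.approx(expected, rel=5e-3)

    def test_composite_area_grows_during_expansion(self, water, jet):
        train = cm.train_from_jet(jet)
        areas = []
        for k in (2, 4, 6):
            x, r = cm.superposed_train_profile(
                train, water, k * train.period, include_surface_tension=False
            )
            areas.append(cm.projected_area(x, r))
        assert areas[0] < areas[1] < areas[2]

    def test_water_composite_matches_parabola_early(self, water, jet):
        train = cm.train_from_jet(jet)
        t = 8 * train.period
        x, r_train = cm.superposed_train_profile(
            train, water, t, include_surface_tension=False
        )
        u_c = 0.5 * jet.U_0
        r_eq = cm.inertial_profile(x, t, jet, u_c)
        sel = (x > 0.02 * u_c * t) & (x < 0.7 * u_c * t)
        rel = np.abs(r_train[sel] - r_eq[sel]) / r_eq[sel]
        assert rel.max() < 0.10

    def test_viscous_target_narrower_than_parabola(self, materials, jet):
        glyc = materials["glycerol_78wt"]
        train = cm.train_from_jet(jet)
        t = 8 * train.period
        x, r_train = cm.superposed_train_profile(
            train, glyc, t, include_surface_tension=False
        )
        r_eq = cm.inertial_profile(x, t, jet, 0.5 * jet.U_0)
        sel = r_eq > 0
        assert np.mean(r_train[sel]) < np.mean(r_eq[sel])


class TestCavityVelocityModel:
    def test_inviscid_density_matched_limit(self):
        jet = JetSpec(1000.0, 1e-4, 20.0)
        ideal = Material("ideal", 1000.0, 1e-12, 0.072)
        assert cm.cavity_velocity_model(jet, ideal) == pytest.approx(
            0.5 * jet.U_0, rel=1e-6
        )

    def test_nonincreasing_in_viscosity(self, jet):
        prev = None
        for mu in (1e-4, 1e-3, 1e-2, 1e-1):
            u = cm.cavity_velocity_model(jet, Material("m", 1000.0, mu, 0.072))
            assert prev is None or u <= prev
            prev = u

    def test_table_liquids_below_half(self, materials, jet):
        for m in materials.values():
            ratio = cm.cavity_velocity_model(jet, m) / jet.U_0
            assert 0.0 < ratio < 0.5

    def test_zero_speed(self, water):
        assert cm.cavity_velocity_model(JetSpec(1000.0, 1e-4, 0.0), water) == 0.0


def test_inertial_trajectory_bookkeeping(water, jet):
    t = np.linspace(0, 3e-4, 40)
    traj = cm.inertial_trajectory(jet, water, t)
    areas = traj.area_series()
    assert traj.A_max == pytest.approx(areas.max())
    assert traj.L_max == pytest.approx(traj.front.max())
    assert np.all(traj.profiles >= 0)
    frame = traj.to_frame()
    assert set(frame.columns) == {"t_s", "x_m", "R_m"}
    assert len(frame) == t.size * traj.x.size
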
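"""Reduced-order transport solver: kinematics, oracles, conservation."""

import numpy as np
import pytest

from corodisp import _solver
from corodisp.dispersion import dispersion_profile, integral_moments, \
    vtf_variance
from corodisp.errors import ConfigurationError, DomainError
from corodisp.synthflow import (GammaVariateAIF, aif_value, constant_waveform,
                                make_waveform)
from corodisp.transport import (ConcentrationRecord, FluidProperties,
                                TransportGrid, VelocityModel, bulk_velocity,
                                simulate_path, simulate_transport,
                                straight_tube_path, velocity_profile)


class TestBulkVelocity:
    def test_lmca_span_carries_full_inlet_velocity(self, geometry, scenarios):
        sc = scenarios["fullAR_rest_constant"]
        p = geometry.path("LAD", sc.outflow_fraction("LAD"))
        wf = sc.inlet_waveform()
        assert bulk_velocity(5e-3, 0.0, sc, p, wf) == pytest.approx(0.200)

    def test_stenosis_throat_speedup_is_five_fold(self, geometry, scenarios):
        sc = scenarios["fullAR_rest_constant"]
        p = geometry.path("LAD", sc.outflow_fraction("LAD"))
        wf = sc.inlet_waveform()
        v_branch = bulk_velocity(15e-3, 0.0, sc, p, wf)
        v_throat = bulk_velocity(35e-3, 0.0, sc, p, wf)
        assert v_throat / v_branch == pytest.approx(1 / 0.2, rel=1e-9)

    def test_time_average_equals_constant_mode(self, geometry, scenarios):
        sc_p = scenarios["fullAR_rest_pulsatile"]
        sc_c = scenarios["fullAR_rest_constant"]
        p = geometry.path("LCX", 0.5)
        t = np.linspace(0, sc_p.period, 2001)
        v_puls = bulk_velocity(50e-3, t, sc_p, p, sc_p.inlet_waveform())
        v_const = bulk_velocity(50e-3, 0.0, sc_c, p, sc_c.inlet_waveform())
        assert np.trapezoid(v_puls, t) / sc_p.period == \
            pytest.approx(v_const, rel=1e-4)

    def test_outside_path_rejected(self, geometry, scenarios):
        sc = scenarios["fullAR_rest_constant"]
        p = geometry.path("LAD", 0.5)
        with pytest.raises(DomainError):
            bulk_velocity(0.5, 0.0, sc, p, sc.inlet_waveform())


class TestVelocityProfile:
    def test_parabolic_centerline_and_wall(self):
        tube = straight_tube_path(2e-3, 0.05)
        wf = constant_waveform(1.0, 0.1)
        model = VelocityModel("parabolic")
        u0 = velocity_profile(0.0, 0.03, 0.0, model, FluidProperties(),
                              path=tube, waveform=wf)
        uw = velocity_profile(1.0, 0.03, 0.0, model, FluidProperties(),
                              path=tube, waveform=wf)
        assert u0 == pytest.approx(0.2, rel=1e-9)
        assert uw == pytest.approx(0.0, abs=1e-12)

    def test_womersley_steady_reduces_to_parabolic(self):
        tube = straight_tube_path(1.78e-3, 0.05)
        wf = constant_waveform(1.0, 0.1)
        eta = np.linspace(0, 1, 33)
        uw = velocity_profile(eta, 0.03, 0.2, VelocityModel("womersley"),
                              FluidProperties(), path=tube, waveform=wf)
        up = velocity_profile(eta, 0.03, 0.2, VelocityModel("parabolic"),
                              FluidProperties(), path=tube, waveform=wf)
        np.testing.assert_allclose(uw, up, rtol=1e-6, atol=1e-12)

    def test_womersley_integrates_to_bulk_velocity(self):
        """alpha ~ 2.3 oscillatory profile must satisfy continuity at every
        stored phase of the cycle."""
        tube = straight_tube_path(1.78e-3, 0.05)
        wf = make_waveform(1.0, 0.15)
        eta = np.linspace(0, 1, 801)
        fluid = FluidProperties()
        alpha = 1.78e-3 * np.sqrt(2 * np.pi / 1.0
                                  / fluid.kinematic_viscosity)
        assert 2.0 < alpha < 2.6
        for t in (0.1, 0.37, 0.62, 0.9):
            u = velocity_profile(eta, 0.03, t, VelocityModel("womersley"),
                                 fluid, path=tube, waveform=wf)
            mean = 2.0 * np.trapezoid(u * eta, eta)
            assert mean == pytest.approx(float(wf.value(t)), rel=2e-3)

    def test_no_slip_for_developed_profiles(self):
        tube = straight_tube_path(1.78e-3, 0.05)
        wf = make_waveform(1.0, 0.15)
        u = velocity_profile(1.0, 0.04, 0.3, VelocityModel("womersley"),
                             FluidProperties(), path=tube, waveform=wf)
        assert abs(u) < 1e-10

    def test_eta_outside_unit_interval_rejected(self):
        tube = straight_tube_path(1.78e-3, 0.05)
        wf = constant_waveform(1.0, 0.1)
        with pytest.raises(DomainError):
            velocity_profile(1.5, 0.03, 0.0, VelocityModel("plug"),
                             FluidProperties(), path=tube, waveform=wf)


class TestPlugAdvection:
    def test_outlet_is_delayed_inlet(self, plug_tube_run):
        tube, aif, recs, _ = plug_tube_run
        outlet = recs[-1]
        delay = tube.total_length / 0.2
        expected = aif_value(outlet.times - delay, aif)
        scale = np.max(expected)
        assert np.max(np.abs(outlet.ybar - expected)) < 0.02 * scale

    def test_mass_conserved_to_machine_precision(self, plug_tube_run):
        *_, quality = plug_tube_run
        assert quality["mass_drift_rel"] < 1e-10

    def test_maximum_principle(self, plug_tube_run):
        _, aif, recs, quality = plug_tube_run
        peak = max(aif_value(np.linspace(0, 40, 4001), aif))
        assert quality["max_overshoot"] < 1e-6
        for rec in recs:
            assert rec.ybar.max() <= peak + 1e-6


class TestLaminarRtdOracle:
    def test_flux_weighted_outlet_matches_analytic_rtd(self):
        """Steady Poiseuille flow with negligible diffusion: the flux-
        weighted outlet response is the laminar residence-time density
        E(t) = tau^2/(2 t^3) for t >= tau/2, compared through windowed
        moments against a brute-force convolution of the analytic kernel."""
        L, u = 0.02, 0.1
        tube = straight_tube_path(1.78e-3, L, inlet_span=1e-3)
        wf = constant_waveform(1.0, u)
        aif = GammaVariateAIF(a=1.0, b=4.0, c=40.0, t0=0.5)
        grid = TransportGrid(n_radial=32, axial_spacing=0.4e-3)
        recs, _ = simulate_path(tube, wf, aif, grid=grid,
                                model=VelocityModel("parabolic"),
                                duration=12.0,
                                fluid=FluidProperties(diffusion=1e-14),
                                averaging="flux")
        outlet, inlet = recs[-1], recs[0]
        t = outlet.times
        tau = L / u
        E = np.where(t >= tau / 2, tau**2 / (2 * np.clip(t, 1e-9, None)**3),
                     0.0)
        dt = t[1] - t[0]
        oracle = np.convolve(aif_value(t, aif), E)[:t.size] * dt
        mi = integral_moments(inlet)
        s2_sim, mvtt_sim = vtf_variance(integral_moments(outlet), mi)
        s2_ora, mvtt_ora = vtf_variance(
            integral_moments(ConcentrationRecord("t", L, False, t, oracle)),
            mi)
        assert mvtt_sim == pytest.approx(mvtt_ora, rel=0.05)
        assert s2_sim == pytest.approx(s2_ora, rel=0.10)


class TestSolverContracts:
    def test_numba_and_numpy_backends_agree(self):
        tube = straight_tube_path(1.78e-3, 0.04)
        wf = make_waveform(1.0, 0.15)
        aif = GammaVariateAIF().with_t0(2.0)
        outs = {}
        for backend in ("numpy", "numba"):
            grid = TransportGrid(n_radial=16, axial_spacing=1e-3,
                                 backend=backend)
            recs, _ = simulate_path(tube, wf, aif, grid=grid,
                                    model=VelocityModel("developing"),
                                    duration=12.0)
            outs[backend] = np.stack([r.ybar for r in recs])
        np.testing.assert_allclose(outs["numba"], outs["numpy"],
                                   rtol=1e-12, atol=1e-16)

    def test_branch_mass_conservation_across_bifurcation(self, geometry,
                                                         scenarios):
        """Flow-weighted outlet doses over both branches recover the inlet
        dose within 0.5% (finite window)."""
        sc = scenarios["fullAR_rest_constant"]
        grid = TransportGrid(n_radial=16, axial_spacing=1.5e-3)
        res = simulate_transport(geometry, sc, grid=grid)
        for branch in ("LAD", "LCX"):
            assert res.mass_drift[branch] < 0.005

    def test_axial_grid_convergence_of_outlet_variance(self):
        """Doubling the axial resolution changes outlet sigma2 by < 5%."""
        tube = straight_tube_path(1.78e-3, 0.03)
        wf = constant_waveform(1.0, 0.15)
        aif = GammaVariateAIF().with_t0(1.0)
        s2 = {}
        for dz in (1.0e-3, 0.5e-3):
            grid = TransportGrid(n_radial=16, axial_spacing=dz)
            recs, _ = simulate_path(tube, wf, aif, grid=grid,
                                    model=VelocityModel("developing"),
                                    duration=35.0)
            s2[dz] = dispersion_profile(recs).sigma2[-1]
        assert abs(s2[0.5e-3] - s2[1.0e-3]) / s2[0.5e-3] < 0.05

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            TransportGrid(n_radial=8)
        with pytest.raises(ConfigurationError):
            TransportGrid(time_step=0.02)
        with pytest.raises(ConfigurationError):
            TransportGrid(backend="fortran")

    def test_graded_mesh_hits_stenosis_and_refines(self, geometry):
        p = geometry.path("LAD", 0.5)
        zf = _solver.build_axial_faces(p, 1e-3, 3.0, 1.3)
        dz = np.diff(zf)
        throat = 35e-3
        near = dz[(zf[:-1] > throat - 2e-3) & (zf[:-1] < throat + 2e-3)]
        far = dz[zf[:-1] < 5e-3]
        assert near.mean() < far.mean() / 2.0
        assert np.any(np.isclose(zf, p.bifurcation_z, atol=1e-12))
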
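"""Multipath kinetic model: operators, BTEX limits, forward-model laws."""

import numpy as np
import pytest

from corodisp.errors import ConfigurationError, DomainError
from corodisp.kinetics import (KineticParams, btex_unit,
                               lagged_normal_weights, mmid4_forward,
                               sample_per_cycle, vessel_operator)
from corodisp.synthflow import GammaVariateAIF, aif_value


def _impulse(n, dt):
    x = np.zeros(n)
    x[0] = 1.0 / dt
    return x


def _moments(t, y):
    m0 = np.trapezoid(y, t)
    m1 = np.trapezoid(t * y, t) / m0
    var = np.trapezoid((t - m1) ** 2 * y, t) / m0
    return m0, m1, var


class TestFlowHeterogeneity:
    def test_unit_mean_and_prescribed_dispersion(self):
        het = lagged_normal_weights(0.55, 20)
        assert (het.w * het.f).sum() == pytest.approx(1.0, abs=1e-12)
        assert het.relative_dispersion == pytest.approx(0.55, rel=0.02)
        assert het.w.sum() == pytest.approx(1.0)
        assert het.f.min() > 0

    def test_right_skewed(self):
        het = lagged_normal_weights(0.55, 20)
        skew = (het.w * (het.f - 1.0) ** 3).sum()
        assert skew > 0

    def test_small_rd_limit_is_homogeneous(self):
        het = lagged_normal_weights(0.02, 20)
        np.testing.assert_allclose(het.f, 1.0, atol=0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            lagged_normal_weights(0.0, 20)
        with pytest.raises(ConfigurationError):
            lagged_normal_weights(0.5, 1)


class TestVesselOperator:
    def test_small_rd_degenerates_to_pure_delay(self):
        dt = 0.01
        t = dt * np.arange(4000)
        y = aif_value(t, GammaVariateAIF(t0=2.0))
        out = vessel_operator(y, dt, 0.02, 1.0, rd=1e-6)
        expected = aif_value(t - 1.2, GammaVariateAIF(t0=2.0))
        assert np.max(np.abs(out - expected)) < 1e-3 * y.max()

    def test_impulse_response_moments(self):
        dt = 0.01
        out = vessel_operator(_impulse(6000, dt), dt, 0.02, 1.0, 0.48)
        t = dt * np.arange(6000)
        m0, mean, var = _moments(t, out)
        assert m0 == pytest.approx(1.0, abs=1e-3)
        assert mean == pytest.approx(1.2, rel=0.01)
        assert np.sqrt(var) / mean == pytest.approx(0.48, rel=0.01)

    def test_series_transit_times_add(self):
        dt = 0.01
        n = 8000
        out1 = vessel_operator(_impulse(n, dt), dt, 0.02, 1.0, 0.48)
        out2 = vessel_operator(out1, dt, 0.03, 1.0, 0.48)
        t = dt * np.arange(n)
        _, mean, _ = _moments(t, out2)
        assert mean == pytest.approx((0.02 + 0.03) * 60, rel=0.01)

    def test_kernel_window_guard(self):
        dt = 0.01
        with pytest.raises(DomainError):
            vessel_operator(_impulse(200, dt), dt, 0.5, 1.0, 0.48)


class TestBtexUnit:
    dt = 0.02

    def _pulse(self, n):
        t = self.dt * np.arange(n)
        p = np.exp(-0.5 * ((t - 2.0) / 0.3) ** 2)
        return t, p / (p.sum() * self.dt)

    def test_intravascular_limit_ps_zero(self):
        """PS = 0: pure vascular transit V_p/F, dose conserved, washout."""
        t, pulse = self._pulse(6000)
        out, content = btex_unit(pulse, self.dt, 1.0, 0.04, 0.35, 1e-9)
        m0, mean, _ = _moments(t, out)
        assert m0 == pytest.approx(1.0, abs=5e-3)
        assert mean - 2.0 == pytest.approx(0.04 * 60, rel=0.02)
        assert content[-1] == pytest.approx(0.0, abs=1e-6)

    def test_flow_limited_ps_infinity_surrogate(self):
        """PS >> F: behaves as one well-mixed space of volume V_p + V_isf."""
        t, pulse = self._pulse(9000)
        out, _ = btex_unit(pulse, self.dt, 1.0, 0.04, 0.35, 1000.0)
        _, mean, _ = _moments(t, out)
        assert mean - 2.0 == pytest.approx((0.04 + 0.35) * 60, rel=0.02)

    def test_dose_and_mean_transit_for_finite_ps(self):
        """Extracellular tracer is not consumed: outflow dose equals inflow
        dose and the mean transit is V_total/F for any PS."""
        t, pulse = self._pulse(12000)
        out, _ = btex_unit(pulse, self.dt, 1.0, 0.04, 0.35, 1.0)
        m0, mean, _ = _moments(t, out)
        assert m0 == pytest.approx(1.0, abs=5e-3)
        assert mean - 2.0 == pytest.approx((0.04 + 0.35) * 60, rel=0.02)

    def test_chain_integrator_against_scipy(self):
        """Dual route: the RK4 segment-chain integrator must agree with an
        independent stiff ODE solve of the same exchange equations."""
        from scipy.integrate import solve_ivp

        nseg = 9
        flow, vp, visf, ps = 1.5, 0.04, 0.35, 1.0
        t, pulse = self._pulse(2500)
        out, content = btex_unit(pulse, self.dt, flow, vp, visf, ps,
                                 n_segments=nseg)
        a = nseg * (flow / 60.0) / vp
        k1 = (ps / 60.0) / vp
        k2 = (ps / 60.0) / visf

        def rhs(tt, y):
            cp, ci = y[:nseg], y[nseg:]
            cin = np.interp(tt, t, pulse)
            up = np.concatenate(([cin], cp[:-1]))
            return np.concatenate([a * (up - cp) - k1 * (cp - ci),
                                   k2 * (cp - ci)])

        sol = solve_ivp(rhs, (0, t[-1]), np.zeros(2 * nseg), method="LSODA",
                        t_eval=t, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(out, sol.y[nseg - 1], atol=5e-4 * out.max())
        ref_content = vp * sol.y[:nseg].mean(axis=0) \
            + visf * sol.y[nseg:].mean(axis=0)
        np.testing.assert_allclose(content, ref_content,
                                   atol=5e-4 * content.max())


class TestForwardModel:
    def setup_method(self):
        self.t = np.arange(0, 60, 0.025)
        self.aif = aif_value(self.t, GammaVariateAIF().with_t0(3.0))

    def test_zero_input_gives_zero_output(self):
        tc = mmid4_forward(self.t, np.zeros_like(self.t), KineticParams())
        assert np.all(tc.q == 0)

    def test_linearity(self):
        p = KineticParams()
        a = mmid4_forward(self.t, self.aif, p)
        b = mmid4_forward(self.t, 2.0 * self.aif + 0.0, p)
        np.testing.assert_allclose(b.q, 2.0 * a.q, rtol=1e-9, atol=1e-12)

    def test_dose_conservation_long_window(self):
        """All injected tracer eventually leaves through the veins."""
        t = np.arange(0, 400, 0.05)
        y = aif_value(t, GammaVariateAIF().with_t0(3.0))
        tc = mmid4_forward(t, y, KineticParams())
        assert np.trapezoid(tc.outflow, t) == pytest.approx(
            np.trapezoid(y, t), rel=5e-3)
        # washout: the slowest pathway (f ~ 0.09) has a ~270 s transit, so
        # a small residue remains at 400 s
        assert tc.q[-1] < 2e-3 * tc.q.max()

    def test_mean_transit_is_total_volume_over_flow(self):
        t = np.arange(0, 400, 0.05)
        y = aif_value(t, GammaVariateAIF().with_t0(3.0))
        p = KineticParams()
        tc = mmid4_forward(t, y, p)
        _, m_in, _ = _moments(t, y)
        _, m_out, _ = _moments(t, tc.outflow)
        assert m_out - m_in == pytest.approx(p.total_volume / (1.0 / 60.0),
                                             rel=0.02)

    def test_wider_input_kernel_flattens_peak(self):
        """Pre-dispersing the AIF can only lower the tissue-curve peak."""
        p = KineticParams()
        base = mmid4_forward(self.t, self.aif, p).q.max()
        dt = self.t[1] - self.t[0]
        for tau in (0.5, 1.0, 2.0):
            k = np.exp(-self.t / tau) / tau
            k /= k.sum() * dt
            blurred = np.convolve(self.aif, k)[:self.t.size] * dt
            peak = mmid4_forward(self.t, blurred, p).q.max()
            assert peak <= base * (1.0 + 1e-9)

    def test_self_convergence_of_time_step(self):
        """Halving the sampling interval moves the peak by < 1%."""
        p = KineticParams()
        coarse = mmid4_forward(self.t, self.aif, p)
        t2 = np.arange(0, 60, 0.0125)
        fine = mmid4_forward(t2, aif_value(t2, GammaVariateAIF().with_t0(3.0)),
                             p)
        assert coarse.q.max() == pytest.approx(fine.q.max(), rel=0.01)
        assert self.t[coarse.q.argmax()] == pytest.approx(
            t2[fine.q.argmax()], abs=0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            KineticParams(mbf=-1)
        with pytest.raises(ConfigurationError):
            KineticParams(rd_flow=1.5)
        with pytest.raises(ConfigurationError):
            mmid4_forward(self.t[::2], self.aif[::3], KineticParams())


class TestSamplePerCycle:
    def test_44_cycles_span_43_seconds(self):
        t = np.arange(0, 60, 0.01)
        tk, vk = sample_per_cycle(t, np.sin(t), 1.0, 44)
        assert tk.size == 44
        assert tk[-1] - tk[0] == pytest.approx(43.0)

    def test_constant_curve_samples_constant(self):
        t = np.arange(0, 50, 0.01)
        _, vk = sample_per_cycle(t, np.full_like(t, 2.5), 1.0, 44)
        np.testing.assert_allclose(vk, 2.5)

    def test_phase_shift_by_full_period_slides_lattice(self):
        t = np.arange(0, 60, 0.01)
        v = np.cos(0.3 * t)
        _, a = sample_per_cycle(t, v, 1.0, 10, phase=0.0)
        _, b = sample_per_cycle(t, v, 1.0, 10, phase=1.0)
        np.testing.assert_allclose(a[1:], b[:-1], atol=1e-12)

    def test_insufficient_coverage_rejected(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(DomainError):
            sample_per_cycle(t, np.sin(t), 1.0, 44)
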
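"""Waveform synthesis, scenario table, and the gamma-variate LV bolus."""

import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from corodisp.errors import ConfigurationError, DomainError
from corodisp.synthflow import (GammaVariateAIF, aif_moments, aif_value,
                                branch_inlet_mean_velocity, constant_waveform,
                                make_waveform, scenario_table)


class TestWaveform:
    def test_mean_and_peak_contracts(self):
        wf = make_waveform(1.0, 0.200, peak_to_mean=1.75)
        tz = np.trapezoid(wf.samples, wf.times) / wf.period
        assert tz == pytest.approx(0.200, rel=1e-6)
        assert wf.samples.max() == pytest.approx(0.350, rel=1e-3)

    def test_nonnegative_and_periodic(self):
        wf = make_waveform(0.9, 0.46, peak_to_mean=1.75)
        assert wf.samples.min() >= 0.0
        assert wf.samples[0] == wf.samples[-1]

    def test_scaling_is_linear(self):
        wf = make_waveform(1.0, 0.2)
        assert wf.scaled(2.3).mean == pytest.approx(0.46)
        np.testing.assert_allclose(wf.scaled(2.3).samples, 2.3 * wf.samples)

    def test_diastolic_dominance(self):
        # the maximum sits in the diastolic window, after systole
        wf = make_waveform(1.0, 0.2, systolic_fraction=0.35)
        assert wf.times[np.argmax(wf.samples)] > 0.35

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ConfigurationError):
            make_waveform(1.0, 0.2, peak_to_mean=0.9)  # peak below mean
        with pytest.raises(ConfigurationError):
            make_waveform(1.0, 0.2, peak_to_mean=5.0)  # needs negative baseline

    def test_constant_mode_has_zero_temporal_variance(self):
        wf = constant_waveform(1.0, 0.2)
        assert wf.is_constant
        assert np.ptp(wf.samples) == 0.0

    def test_harmonics_reconstruct_waveform(self):
        wf = make_waveform(1.0, 0.2, n_samples=256)
        u_hat, omega = wf.harmonics(n_max=40)
        t = wf.times[:-1]
        rec = sum(np.real(u_hat[n] * np.exp(1j * n * omega * t))
                  for n in range(u_hat.size))
        # the lobed waveform is not band-limited; 40 harmonics capture it
        # to ~0.01% of the mean velocity
        np.testing.assert_allclose(rec, wf.samples[:-1], atol=1e-4 * 0.2)


class TestScenarioTable:
    def test_eight_scenarios(self):
        assert len(scenario_table()) == 8

    @pytest.mark.parametrize("ar,state,f_lad,scale,vmean,period", [
        ("full", "rest", 0.500, 1.000, 0.200, 1.0),
        ("full", "hyperemia", 0.500, 2.300, 0.460, 0.9),
        ("limited", "rest", 0.453, 0.915, 0.183, 1.0),
        ("limited", "hyperemia", 0.351, 1.773, 0.355, 0.9),
    ])
    def test_boundary_condition_rows(self, scenarios, ar, state, f_lad,
                                     scale, vmean, period):
        for mode in ("pulsatile", "constant"):
            sc = scenarios[f"{ar}AR_{state}_{mode}"]
            assert sc.outflow_fraction_lad == pytest.approx(f_lad)
            assert sc.scale_factor == pytest.approx(scale)
            assert sc.mean_inlet_velocity == pytest.approx(vmean, abs=5e-4)
            assert sc.period == period

    def test_hyperemic_heart_rate(self, scenarios):
        sc = scenarios["fullAR_hyperemia_pulsatile"]
        assert 60.0 / sc.period == pytest.approx(66.67, abs=0.01)

    def test_bolus_arrival_after_three_cycles_and_total_duration(self,
                                                                 scenarios):
        assert scenarios["fullAR_rest_pulsatile"].bolus_arrival == 3.0
        assert scenarios["fullAR_rest_pulsatile"].duration == 53.0
        assert scenarios["fullAR_hyperemia_pulsatile"].duration == \
            pytest.approx(52.7)


class TestBranchVelocities:
    def test_full_ar_rest_lad(self, scenarios, geometry):
        v = branch_inlet_mean_velocity(scenarios["fullAR_rest_pulsatile"],
                                       geometry, "LAD")
        assert v == pytest.approx(0.5 * 0.200 * (2.25 / 1.78) ** 2, rel=1e-9)

    def test_limited_ar_velocity_reduction_factor(self, scenarios, geometry):
        """Limited autoregulation cuts the stenosed-branch velocity by 0.829."""
        v_full = branch_inlet_mean_velocity(scenarios["fullAR_rest_constant"],
                                            geometry, "LAD")
        v_lim = branch_inlet_mean_velocity(
            scenarios["limitedAR_rest_constant"], geometry, "LAD")
        assert v_lim / v_full == pytest.approx(0.829, abs=5e-4)

    def test_flow_reserve_ratios(self, scenarios, geometry):
        """Hyperemia/rest velocity ratios: 1.5 stenosed, 2.3 normal (limited AR)."""
        def ratio(ar, branch):
            vh = branch_inlet_mean_velocity(
                scenarios[f"{ar}AR_hyperemia_constant"], geometry, branch)
            vr = branch_inlet_mean_velocity(
                scenarios[f"{ar}AR_rest_constant"], geometry, branch)
            return vh / vr
        assert ratio("limited", "LAD") == pytest.approx(1.5, rel=5e-3)
        assert ratio("limited", "LCX") == pytest.approx(2.3, rel=5e-3)
        assert ratio("full", "LAD") == pytest.approx(2.3, rel=5e-3)
        assert ratio("full", "LCX") == pytest.approx(2.3, rel=5e-3)

    def test_unknown_branch_rejected(self, scenarios, geometry):
        with pytest.raises(DomainError):
            branch_inlet_mean_velocity(scenarios["fullAR_rest_constant"],
                                       geometry, "RCA")


class TestGammaVariateAIF:
    def test_zero_before_and_at_arrival(self):
        aif = GammaVariateAIF(t0=3.0)
        assert aif_value(3.0, aif) == 0.0
        assert aif_value(1.0, aif) == 0.0

    def test_peak_time_is_b_over_c(self):
        aif = GammaVariateAIF()
        assert aif.peak_time == pytest.approx(2.142 / 0.454, rel=1e-9)
        t = np.linspace(0, 30, 30001)
        assert t[np.argmax(aif_value(t, aif))] == pytest.approx(4.718,
                                                                abs=2e-3)

    def test_value_one_second_after_arrival(self):
        aif = GammaVariateAIF()
        assert aif_value(1.0, aif) == pytest.approx(
            1.013e-3 * math.exp(-0.454), rel=1e-9)
        # independent log-domain evaluation
        assert aif_value(1.0, aif) == pytest.approx(
            math.exp(math.log(1.013e-3) - 0.454), rel=1e-12)

    def test_moments_match_gamma_distribution(self):
        aif = GammaVariateAIF(t0=3.0)
        area, mean, var = aif_moments(aif)
        assert mean - 3.0 == pytest.approx(3.142 / 0.454, rel=1e-9)
        assert var == pytest.approx(3.142 / 0.454**2, rel=1e-9)
        # b -> 0 limit degenerates to an exponential
        expo = GammaVariateAIF(a=1.0, b=1e-12, c=0.5)
        assert aif_moments(expo)[2] == pytest.approx(1 / 0.5**2, rel=1e-6)

    def test_numerical_integral_matches_closed_form(self):
        aif = GammaVariateAIF()
        t = np.linspace(0, 120, 12001)
        num = np.trapezoid(aif_value(t, aif), t)
        closed = 1.013e-3 * gamma_fn(3.142) / 0.454**3.142
        assert num == pytest.approx(closed, rel=1e-3)
        assert aif.area == pytest.approx(closed, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            GammaVariateAIF(a=-1.0)
        with pytest.raises(ConfigurationError):
            GammaVariateAIF(t0=-0.1)
        with pytest.raises(DomainError):
            aif_value(float("nan"), GammaVariateAIF())
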
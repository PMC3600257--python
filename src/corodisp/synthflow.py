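"""Synthetic inflow and bolus generators.

Three ingredients drive every simulation:

* a diastolic-dominant pulsatile velocity waveform for the LMCA inlet (a
  parametric stand-in for a phase-contrast-MRI measured pattern; left
  coronary inflow peaks in diastole because systolic wall compression
  throttles the intramural vessels),
* the table of eight flow scenarios -- {full, limited} autoregulation x
  {rest, hyperemia} x {pulsatile, constant} -- with their outflow splits,
  waveform scaling factors and cycle durations,
* the gamma-variate left-ventricular arterial input function (AIF)
  Y(t) = a (t-t0)^b exp(-c (t-t0)) that models the first-pass contrast bolus.

The generators are deterministic; ``seed`` is reserved for an optional
measurement-noise add-on which is off by default.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

from .errors import ConfigurationError, DomainError
from .geometry import BifurcationGeometry

__all__ = [
    "VelocityWaveform",
    "FlowScenario",
    "GammaVariateAIF",
    "make_waveform",
    "constant_waveform",
    "scenario_table",
    "branch_inlet_mean_velocity",
    "aif_value",
    "aif_moments",
]

#: Reference mean LMCA inlet velocity at rest [m/s]; Table-1 scaling factors
#: multiply this value.
BASE_MEAN_VELOCITY = 0.200


@dataclass(frozen=True)
class VelocityWaveform:
    """One period of an inlet velocity waveform, uniformly sampled.

    ``samples`` holds n+1 values including both endpoints of the period so
    that periodicity (first == last) is explicit.
    """

    period: float  # [s]
    samples: np.ndarray  # [m/s]
    mean: float  # [m/s] time average

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or s.size < 3:
            raise ConfigurationError("waveform needs >= 3 samples")
        if abs(s[0] - s[-1]) > 1e-9 * max(1.0, abs(s[0])):
            raise ConfigurationError("waveform is not periodic (first != last sample)")
        tz = np.trapezoid(s, dx=self.period / (s.size - 1)) / self.period
        if abs(tz - self.mean) > 1e-6 * max(abs(self.mean), 1e-12):
            raise ConfigurationError("stored mean disagrees with trapezoidal average")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.samples.size)

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.samples) < 1e-12 * max(1.0, abs(self.mean)))

    def value(self, t) -> np.ndarray:
        """Velocity at time(s) ``t`` by periodic linear interpolation."""
        tp = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(tp, self.times, self.samples)

    def scaled(self, k: float) -> "VelocityWaveform":
        return VelocityWaveform(self.period, self.samples * k, self.mean * k)

    def harmonics(self, n_max: int = 12) -> tuple[np.ndarray, float]:
        """Complex Fourier coefficients (u_hat[0..n_max], omega).

        u(t) = Re( sum_n u_hat[n] exp(i n omega t) ); u_hat[0] is the mean.
        """
        s = self.samples[:-1]
        coef = np.fft.rfft(s) / s.size
        u_hat = np.zeros(n_max + 1, dtype=complex)
        u_hat[0] = coef[0].real
        m = min(n_max, coef.size - 1)
        u_hat[1:m + 1] = 2.0 * coef[1:m + 1]
        return u_hat, 2.0 * math.pi / self.period

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("t_s,velocity_m_per_s\n")
        for t, v in zip(self.times, self.samples):
            buf.write(f"{t:.6e},{v:.6e}\n")
        return buf.getvalue()


def make_waveform(period: float, mean: float, peak_to_mean: float = 1.75,
                  systolic_fraction: float = 0.35, n_samples: int = 512,
                  seed: int | None = None) -> VelocityWaveform:
    """Deterministic diastolic-dominant inlet waveform.

    A small raised-cosine systolic lobe occupies the first
    ``systolic_fraction`` of the cycle and a larger diastolic lobe the rest,
    on a nonnegative baseline.  The construction is exact: the trapezoidal
    mean equals ``mean`` and the maximum equals ``peak_to_mean * mean``.

    ``seed`` is accepted for interface stability (reserved for an optional
    noise add-on) and does not affect the output.
    """
    del seed
    if peak_to_mean <= 1:
        raise ConfigurationError("peak_to_mean must be > 1")
    if not (0 < systolic_fraction < 1):
        raise ConfigurationError("systolic_fraction must lie in (0, 1)")
    if period <= 0 or mean <= 0:
        raise ConfigurationError("period and mean must be > 0")
    sys_over_dia = 0.45  # systolic lobe amplitude relative to diastolic lobe
    s = systolic_fraction
    peak = peak_to_mean * mean
    # mean of the shape: baseline + half-amplitude of each hann lobe weighted
    # by its duration fraction
    lobe_mean_coef = 0.5 * (sys_over_dia * s + (1.0 - s))
    a_dia = (peak - mean) / (1.0 - lobe_mean_coef)
    base = peak - a_dia
    if base < 0:
        raise ConfigurationError(
            "infeasible peak_to_mean/systolic_fraction combination "
            "(would require a negative baseline)")
    t = np.linspace(0.0, period, n_samples + 1)
    x = t / period
    wave = np.full(t.size, base)
    in_sys = x < s
    wave[in_sys] += (sys_over_dia * a_dia
                     * 0.5 * (1.0 - np.cos(2.0 * np.pi * x[in_sys] / s)))
    in_dia = ~in_sys
    wave[in_dia] += a_dia * 0.5 * (1.0 - np.cos(2.0 * np.pi * (x[in_dia] - s)
                                                / (1.0 - s)))
    wave[-1] = wave[0]
    return VelocityWaveform(period, wave, mean)


def constant_waveform(period: float, mean: float,
                      n_samples: int = 8) -> VelocityWaveform:
    """Constant-velocity waveform with the given time average."""
    return VelocityWaveform(period, np.full(n_samples + 1, float(mean)), mean)


@dataclass(frozen=True)
class FlowScenario:
    """One of the eight simulated flow conditions."""

    autoregulation: str  # "full" | "limited"
    state: str  # "rest" | "hyperemia"
    mode: str  # "pulsatile" | "constant"
    outflow_fraction_lad: float
    outflow_fraction_lcx: float
    scale_factor: float
    period: float  # [s] cardiac cycle duration

    def __post_init__(self) -> None:
        if self.autoregulation not in ("full", "limited"):
            raise ConfigurationError("autoregulation must be 'full' or 'limited'")
        if self.state not in ("rest", "hyperemia"):
            raise ConfigurationError("state must be 'rest' or 'hyperemia'")
        if self.mode not in ("pulsatile", "constant"):
            raise ConfigurationError("mode must be 'pulsatile' or 'constant'")
        if abs(self.outflow_fraction_lad + self.outflow_fraction_lcx - 1.0) > 1e-9:
            raise ConfigurationError("outflow fractions must sum to 1")

    @property
    def name(self) -> str:
        return f"{self.autoregulation}AR_{self.state}_{self.mode}"

    @property
    def mean_inlet_velocity(self) -> float:
        """Time-averaged LMCA inlet velocity [m/s]."""
        return self.scale_factor * BASE_MEAN_VELOCITY

    @property
    def bolus_arrival(self) -> float:
        """Bolus arrival delay t0 [s]: the end of three cardiac cycles."""
        return 3.0 * self.period

    @property
    def duration(self) -> float:
        """Total simulated duration [s]: t0 plus 50 s of bolus transport."""
        return self.bolus_arrival + 50.0

    def outflow_fraction(self, branch: str) -> float:
        key = branch.upper()
        if key == "LAD":
            return self.outflow_fraction_lad
        if key == "LCX":
            return self.outflow_fraction_lcx
        raise DomainError(f"unknown branch {branch!r}")

    def inlet_waveform(self, peak_to_mean: float = 1.75,
                       systolic_fraction: float = 0.35,
                       n_samples: int = 512) -> VelocityWaveform:
        """The LMCA inlet waveform for this scenario.

        Constant mode uses the time average of the corresponding pulsatile
        pattern (zero temporal variance).
        """
        if self.mode == "constant":
            return constant_waveform(self.period, self.mean_inlet_velocity)
        return make_waveform(self.period, self.mean_inlet_velocity,
                             peak_to_mean, systolic_fraction, n_samples)

    @property
    def true_mbf(self) -> dict[str, float]:
        """Reference myocardial blood flow [mL/(g min)] per branch.

        Rest is 1 everywhere; at hyperemia the normal territory reaches 2.3
        while a territory fed through the stenosis under limited
        autoregulation only reaches 1.5.
        """
        if self.state == "rest":
            return {"LAD": 1.0, "LCX": 1.0}
        if self.autoregulation == "full":
            return {"LAD": 2.3, "LCX": 2.3}
        return {"LAD": 1.5, "LCX": 2.3}


def scenario_table() -> list[FlowScenario]:
    """The eight scenarios: AR set x physiologic state x flow mode.

    Flow splits and waveform scaling factors: full autoregulation keeps a
    50/50 split (scale 1.000 rest -> 0.200 m/s, 2.300 hyperemia -> 0.460 m/s);
    limited autoregulation shifts flow away from the stenosed LAD
    (45.3/54.7, scale 0.915 -> 0.183 m/s at rest; 35.1/64.9, scale 1.773 ->
    0.355 m/s at hyperemia).  The cardiac cycle shortens from 1.0 s to 0.9 s
    at hyperemia (60 -> 66.67 bpm).
    """
    rows = [
        ("full", "rest", 0.500, 0.500, 1.000, 1.0),
        ("full", "hyperemia", 0.500, 0.500, 2.300, 0.9),
        ("limited", "rest", 0.453, 0.547, 0.915, 1.0),
        ("limited", "hyperemia", 0.351, 0.649, 1.773, 0.9),
    ]
    out = []
    for ar, state, f_lad, f_lcx, scale, period in rows:
        for mode in ("pulsatile", "constant"):
            out.append(FlowScenario(ar, state, mode, f_lad, f_lcx, scale, period))
    return out


def scenario_table_csv() -> str:
    """Scenario table as CSV with the boundary-condition columns."""
    buf = io.StringIO()
    buf.write("autoregulation,state,mode,outflow_lad_pct,outflow_lcx_pct,"
              "scale_factor,mean_velocity_m_per_s,period_s\n")
    for sc in scenario_table():
        buf.write(f"{sc.autoregulation},{sc.state},{sc.mode},"
                  f"{100 * sc.outflow_fraction_lad:.1f},"
                  f"{100 * sc.outflow_fraction_lcx:.1f},"
                  f"{sc.scale_factor:.3f},{sc.mean_inlet_velocity:.3f},"
                  f"{sc.period:.1f}\n")
    return buf.getvalue()


def branch_inlet_mean_velocity(scenario: FlowScenario,
                               geometry: BifurcationGeometry,
                               branch: str) -> float:
    """Time-mean bulk velocity [m/s] just downstream of the bifurcation.

    Continuity on rigid walls: v_branch = f * v_in * A_LMCA / A_branch.
    """
    key = branch.upper()
    if key == "LAD":
        a_branch = geometry.lad.area
    elif key == "LCX":
        a_branch = geometry.lcx.area
    else:
        raise DomainError(f"unknown branch {branch!r}")
    return (scenario.outflow_fraction(key) * scenario.mean_inlet_velocity
            * geometry.lmca.area / a_branch)


@dataclass(frozen=True)
class GammaVariateAIF:
    """Gamma-variate LV bolus: Y(t) = a (t-t0)^b exp(-c (t-t0)) for t > t0.

    Defaults are a volunteer-fit: a = 1.013e-3 (mass fraction units),
    b = 2.142, c = 0.454 1/s.  ``t0`` delays the bolus arrival; the solver
    conventionally sets it to the end of three cardiac cycles.
    """

    a: float = 1.013e-3
    b: float = 2.142
    c: float = 0.454  # [1/s]
    t0: float = 0.0  # [s]

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ConfigurationError("a, b, c must all be > 0")
        if self.t0 < 0:
            raise ConfigurationError("t0 must be >= 0")

    def with_t0(self, t0: float) -> "GammaVariateAIF":
        return GammaVariateAIF(self.a, self.b, self.c, t0)

    @property
    def peak_time(self) -> float:
        """Time of the bolus maximum, t0 + b/c."""
        return self.t0 + self.b / self.c

    @property
    def area(self) -> float:
        """Closed-form integral over (t0, inf): a Gamma(b+1) / c^(b+1)."""
        return self.a * gamma_fn(self.b + 1.0) / self.c ** (self.b + 1.0)

    def __call__(self, t):
        return aif_value(t, self)

    def to_csv(self, t_end: float = 120.0, dt: float = 0.01) -> str:
        t = np.arange(0.0, t_end + 0.5 * dt, dt)
        y = aif_value(t, self)
        buf = io.StringIO()
        buf.write("t_s,mass_fraction\n")
        for ti, yi in zip(t, y):
            buf.write(f"{ti:.6e},{yi:.6e}\n")
        return buf.getvalue()


def aif_value(t, aif: GammaVariateAIF):
    """Evaluate the gamma-variate bolus at time(s) ``t`` (0 for t <= t0)."""
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise DomainError("t must be finite")
    dt = t_arr - aif.t0
    with np.errstate(invalid="ignore"):
        y = np.where(dt > 0.0,
                     aif.a * np.power(np.clip(dt, 0.0, None), aif.b)
                     * np.exp(-aif.c * np.clip(dt, 0.0, None)),
                     0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(y)
    return y


def aif_moments(aif: GammaVariateAIF) -> tuple[float, float, float]:
    """Closed-form (area, mean transit, variance) of the bolus curve.

    Viewed as an unnormalized Gamma(b+1, c) density shifted by t0, the
    normalized mean is t0 + (b+1)/c and the variance (b+1)/c^2.  Serves as
    the analytic oracle for the moment-based dispersion analysis.
    """
    mean = aif.t0 + (aif.b + 1.0) / aif.c
    var = (aif.b + 1.0) / aif.c**2
    return aif.area, mean, var
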
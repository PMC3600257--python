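"""End-to-end experiment orchestration.

One call runs the complete study: for every selected flow scenario the
inlet waveform is synthesized, the contrast bolus is transported down both
branch paths, dispersion profiles are extracted, the dispersed outlet input
drives the kinetic model, and the resulting tissue curve is refit with the
undispersed LV input to quantify the MBF/MPR errors.  Everything is
deterministic for a given configuration.

Three resolution profiles trade accuracy for runtime:

* ``full``  -- full geometry, 0.5 mm base axial spacing, 24 radial shells;
* ``desk``   -- full geometry, 1.25 mm spacing, 16 shells (hours -> minutes);
* ``smoke``  -- shortened 20 mm branches, 20 s bolus window, 10 cycles; it
  exercises every stage in seconds and is used by the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import DispersionProfile, dispersion_profile
from .errors import ConfigurationError, DomainError
from .geometry import build_geometry
from .kinetics import KineticParams, lagged_normal_weights
from .perferror import (FitSpec, MPRResult, PerfusionErrorResult, error_mpr,
                        fit_mbf, generate_mctc)
from .synthflow import FlowScenario, GammaVariateAIF, scenario_table
from .transport import (FluidProperties, TransportGrid, VelocityModel,
                        simulate_transport)

__all__ = ["RunConfig", "RunBundle", "run_pipeline", "summarize", "PROFILES"]

logger = logging.getLogger(__name__)

PROFILES: dict[str, dict] = {
    "full": {"axial_spacing": 0.5e-3, "n_radial": 24, "n_cycles": 44,
              "geometry_overrides": {}, "duration_after_t0": 50.0},
    "desk": {"axial_spacing": 1.25e-3, "n_radial": 16, "n_cycles": 44,
             "geometry_overrides": {}, "duration_after_t0": 50.0},
    "smoke": {"axial_spacing": 1.0e-3, "n_radial": 16, "n_cycles": 10,
              "geometry_overrides": {"lad_length_m": 20e-3,
                                     "lcx_length_m": 20e-3,
                                     "stenosis_center_m": 10e-3,
                                     "extension_length_m": 5e-3},
              "duration_after_t0": 20.0},
}


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    profile: str = "desk"
    scenarios: list[str] | None = None    # names or None -> all eight
    geometry_overrides: dict = field(default_factory=dict)
    peak_to_mean: float = 1.75
    systolic_fraction: float = 0.35
    n_radial: int | None = None           # None -> profile default
    axial_spacing: float | None = None
    backend: str = "auto"
    averaging: str = "area"
    profile_kind: str = "developing"
    kinetics: KineticParams = field(default_factory=KineticParams)
    fit: FitSpec = field(default_factory=FitSpec)
    n_cycles: int | None = None
    duration_after_t0: float | None = None
    write_station_curves: bool = True
    station_curve_hz: float = 20.0
    output_dir: str | None = None
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ConfigurationError(
                f"profile must be one of {sorted(PROFILES)}")
        known = {s.name for s in scenario_table()}
        if self.scenarios:
            bad = set(self.scenarios) - known
            if bad:
                raise ConfigurationError(f"unknown scenarios: {sorted(bad)}")

    # resolved settings -----------------------------------------------------

    @property
    def resolved(self) -> dict:
        prof = PROFILES[self.profile]
        geo = dict(prof["geometry_overrides"])
        geo.update(self.geometry_overrides)
        return {
            "n_radial": self.n_radial or prof["n_radial"],
            "axial_spacing": self.axial_spacing or prof["axial_spacing"],
            "n_cycles": self.n_cycles or prof["n_cycles"],
            "duration_after_t0": (self.duration_after_t0
                                  or prof["duration_after_t0"]),
            "geometry_overrides": geo,
        }

    def selected_scenarios(self) -> list[FlowScenario]:
        table = scenario_table()
        if not self.scenarios:
            return table
        return [s for s in table if s.name in set(self.scenarios)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "kinetics" in d and isinstance(d["kinetics"], dict):
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitSpec(**d["fit"])
        return cls(**d)


@dataclass
class ScenarioOutcome:
    scenario: FlowScenario
    profiles: dict[str, DispersionProfile]
    fits: dict[str, PerfusionErrorResult]
    outlet_sigma2: dict[str, float]
    outlet_mvtt: dict[str, float]
    quality: dict[str, dict]
    records: dict | None = None  # station ConcentrationRecords per branch
    mctc: dict | None = None     # (cycle times, cycle-sampled mCTC) per branch


@dataclass
class RunBundle:
    """All artifacts of a pipeline run, with writers for the CSV outputs."""

    config: RunConfig
    outcomes: dict[str, ScenarioOutcome]
    mpr: list[tuple[str, str, str, MPRResult]]  # (ar, mode, branch, result)

    def error_table(self) -> pd.DataFrame:
        rows = []
        for name, oc in self.outcomes.items():
            for branch, fit in oc.fits.items():
                rows.append({
                    "scenario": name, "branch": branch,
                    "mbf_true": fit.mbf_true,
                    "mbf_fit": fit.fitted["mbf"],
                    "ps_fit": fit.fitted["ps"],
                    "delay_fit": fit.fitted["delay"],
                    "vp_fit": fit.fitted["v_p"],
                    "e_mbf": fit.e_mbf,
                    "sigma2_outlet_s2": oc.outlet_sigma2[branch],
                    "mvtt_outlet_s": oc.outlet_mvtt[branch],
                    "converged": fit.converged,
                })
        return pd.DataFrame(rows)

    def mpr_table(self) -> pd.DataFrame:
        rows = [{"autoregulation": ar, "mode": mode, "branch": branch,
                 "mpr_true": r.mpr_true, "mpr_fit": r.mpr_fit,
                 "e_mpr": r.e_mpr}
                for ar, mode, branch, r in self.mpr]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, default=str))
        self.error_table().to_csv(out / "error_table.csv", index=False)
        if self.mpr:
            self.mpr_table().to_csv(out / "mpr_table.csv", index=False)
        for name, oc in self.outcomes.items():
            d = out / name
            d.mkdir(exist_ok=True)
            for branch, prof in oc.profiles.items():
                (d / f"dispersion_{branch}.csv").write_text(prof.to_csv())
            if oc.mctc:
                for branch, (tk, qk) in oc.mctc.items():
                    pd.DataFrame({"t_s": tk, "mctc": qk}).to_csv(
                        d / f"mctc_{branch}.csv", index=False)
            if self.config.write_station_curves and oc.records:
                for branch, recs in oc.records.items():
                    rows = []
                    for rec in recs:
                        step = max(1, int(round(
                            1.0 / (self.config.station_curve_hz
                                   * (rec.times[1] - rec.times[0])))))
                        for t, y in zip(rec.times[::step], rec.ybar[::step]):
                            rows.append((rec.z, rec.excluded, t, y))
                    pd.DataFrame(rows, columns=["z_m", "excluded", "t_s",
                                                "ybar"]).to_csv(
                        d / f"stations_{branch}.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summarize(self), indent=2, default=float))


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the full experiment described by ``config``."""
    res = config.resolved
    geometry = build_geometry(res["geometry_overrides"])
    grid = TransportGrid(n_radial=res["n_radial"],
                         axial_spacing=res["axial_spacing"],
                         backend=config.backend)
    model = VelocityModel(profile_kind=config.profile_kind)
    fluid = FluidProperties()
    het = lagged_normal_weights(config.kinetics.rd_flow,
                                config.kinetics.n_paths)
    scenarios = config.selected_scenarios()
    if not scenarios:
        raise ConfigurationError("no scenarios selected")

    outcomes: dict[str, ScenarioOutcome] = {}
    for sc in scenarios:
        if config.verbosity:
            logger.info("scenario %s", sc.name)
        aif = GammaVariateAIF().with_t0(sc.bolus_arrival)
        duration = sc.bolus_arrival + res["duration_after_t0"]
        waveform = sc.inlet_waveform(config.peak_to_mean,
                                     config.systolic_fraction)
        transport = simulate_transport(
            geometry, sc, aif=aif, fluid=fluid, grid=grid, model=model,
            duration=duration, waveform=waveform)
        profiles: dict[str, DispersionProfile] = {}
        fits: dict[str, PerfusionErrorResult] = {}
        s2_out: dict[str, float] = {}
        mvtt_out: dict[str, float] = {}
        mctcs: dict[str, tuple] = {}
        for branch, recs in transport.records.items():
            prof = dispersion_profile(recs)
            profiles[branch] = prof
            s2_out[branch] = float(prof.sigma2[-1])
            mvtt_out[branch] = float(prof.mvtt[-1])
            outlet = [r for r in recs if not r.excluded][-1]
            params = dataclasses.replace(
                config.kinetics.for_state(sc.state),
                mbf=sc.true_mbf[branch])
            tk, qk, _ = generate_mctc(outlet, params, sc,
                                      n_cycles=res["n_cycles"],
                                      heterogeneity=het)
            mctcs[branch] = (tk, qk)
            fits[branch] = fit_mbf(tk, qk, aif, config.fit, params,
                                   params.mbf, sc.name, branch,
                                   heterogeneity=het)
            if config.verbosity:
                logger.info("  %s: sigma2=%.3f s^2, E_MBF=%+.1f%%",
                            branch, s2_out[branch], 100 * fits[branch].e_mbf)
        outcomes[sc.name] = ScenarioOutcome(sc, profiles, fits, s2_out,
                                            mvtt_out, transport.quality,
                                            records=transport.records,
                                            mctc=mctcs)

    mpr: list[tuple[str, str, str, MPRResult]] = []
    for ar in ("full", "limited"):
        for mode in ("pulsatile", "constant"):
            rest_name = f"{ar}AR_rest_{mode}"
            hyper_name = f"{ar}AR_hyperemia_{mode}"
            if rest_name not in outcomes or hyper_name not in outcomes:
                continue
            for branch in ("LAD", "LCX"):
                rest = outcomes[rest_name].fits.get(branch)
                hyper = outcomes[hyper_name].fits.get(branch)
                if rest is None or hyper is None:
                    continue
                mpr_true = (outcomes[hyper_name].scenario.true_mbf[branch]
                            / outcomes[rest_name].scenario.true_mbf[branch])
                mpr.append((ar, mode, branch,
                            error_mpr(rest, hyper, mpr_true)))

    bundle = RunBundle(config, outcomes, mpr)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def summarize(bundle: RunBundle) -> dict:
    """Headline summary: error ranges, qualitative flags, rank correlation."""
    if not bundle.outcomes:
        raise DomainError("cannot summarize an empty bundle")
    err = bundle.error_table()
    err["mode"] = [bundle.outcomes[s].scenario.mode for s in err["scenario"]]
    err["autoregulation"] = [bundle.outcomes[s].scenario.autoregulation
                             for s in err["scenario"]]
    out: dict = {"n_scenarios": len(bundle.outcomes),
                 "n_fits": int(len(err))}
    for mode, sub in err.groupby("mode"):
        out[f"e_mbf_{mode}_min"] = float(sub["e_mbf"].min())
        out[f"e_mbf_{mode}_max"] = float(sub["e_mbf"].max())
    out["systematic_mbf_underestimation"] = bool((err["e_mbf"] < 0).all())
    if bundle.mpr:
        e_mpr = [r.e_mpr for _, _, _, r in bundle.mpr]
        out["e_mpr_min"] = float(min(e_mpr))
        out["e_mpr_max"] = float(max(e_mpr))
        out["mpr_overestimation"] = bool(min(e_mpr) > 0)
    # dispersion comparisons in the stenotic branch
    s2 = {(bundle.outcomes[s].scenario.autoregulation,
           bundle.outcomes[s].scenario.state,
           bundle.outcomes[s].scenario.mode, b): v
          for s, oc in bundle.outcomes.items()
          for b, v in oc.outlet_sigma2.items()}

    def _pair(cmp_name, key_a, key_b):
        if key_a in s2 and key_b in s2:
            out[cmp_name] = bool(s2[key_a] >= s2[key_b])

    for state in ("rest", "hyperemia"):
        for ar in ("full", "limited"):
            _pair(f"lad_sigma2_const_ge_puls_{ar}_{state}",
                  (ar, state, "constant", "LAD"),
                  (ar, state, "pulsatile", "LAD"))
        for mode in ("pulsatile", "constant"):
            _pair(f"lad_sigma2_limited_ge_full_{state}_{mode}",
                  ("limited", state, mode, "LAD"),
                  ("full", state, mode, "LAD"))
    if len(err) >= 3:
        from scipy.stats import spearmanr
        rho = spearmanr(err["e_mbf"], err["sigma2_outlet_s2"]).statistic
        if np.isfinite(rho):  # degenerate (e.g. all-clipped) runs yield NaN
            out["spearman_embf_sigma2"] = float(rho)
    return out
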
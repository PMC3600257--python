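"""Idealized left-coronary bifurcation geometry.

The left main coronary artery (LMCA) splits into the left anterior descending
(LAD) and the circumflex (LCX) branch.  For the reduced-order transport model
each inlet->outlet route is represented as an axisymmetric *path* with an
axial cross-section area profile A(z): the LMCA span, an abrupt area change at
the bifurcation plane (the physical cross-section area grows by a factor of
about 1.25 there), and the branch span.  The LAD carries a symmetric
cosinusoidal stenosis specified by its *area* reduction.  The 80 degree
branch angle and the 3D bifurcation shape are retained as metadata only; they
do not enter the axisymmetric model.

All lengths are SI (metres).  The default dimensions are literature-based
values for an RCA-dominant male: r_LMCA = 2.25 mm, r_LAD = r_LCX = 1.78 mm,
10 mm LMCA, 100 mm branches, plus a 10 mm outlet extension whose stations are
flagged ``excluded`` and dropped from every analysis.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "VesselSpec",
    "StenosisSpec",
    "BranchPath",
    "BifurcationGeometry",
    "stenosis_area_profile",
    "build_geometry",
    "reynolds_number",
]

#: Default axial distance between analysis stations along a path [m].
STATION_SPACING = 2.5e-3


@dataclass(frozen=True)
class VesselSpec:
    """A straight cylindrical vessel segment."""

    name: str
    radius: float  # [m]
    length: float  # [m] centerline length

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError(f"{self.name}: radius must be > 0")
        if self.length <= 0:
            raise ConfigurationError(f"{self.name}: length must be > 0")

    @property
    def area(self) -> float:
        """Lumen cross-section area [m^2]."""
        return math.pi * self.radius**2


@dataclass(frozen=True)
class StenosisSpec:
    """Symmetric cosinusoidal stenosis defined by fractional *area* reduction.

    ``center`` is the axial position of the throat measured from the
    bifurcation plane along the branch; ``area_reduction`` f in [0, 1) is the
    peak fractional loss of lumen area (f = 0.80 means an 80% area stenosis).
    """

    center: float = 25e-3  # [m] behind the bifurcation
    length: float = 10e-3  # [m] axial extent
    area_reduction: float = 0.80

    def __post_init__(self) -> None:
        if not (0 <= self.area_reduction < 1):
            raise ConfigurationError("area_reduction must satisfy 0 <= f < 1")
        if self.length <= 0:
            raise ConfigurationError("stenosis length must be > 0")


def stenosis_area_profile(z, branch: VesselSpec, sten: StenosisSpec):
    """Lumen area [m^2] at axial position ``z`` along a stenosed branch.

    ``z`` is measured from the branch inlet (the bifurcation plane) and may
    be a scalar or an array.  Outside the stenosis the area is the nominal
    branch area A0; inside it follows the C1-smooth raised-cosine notch

        A(z) = A0 * (1 - f/2 * (1 + cos(2 pi (z - center) / L)))

    whose minimum at the throat is (1 - f) * A0.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < -1e-12) or np.any(z_arr > branch.length + 1e-12):
        raise DomainError("z outside the branch span")
    half = 0.5 * sten.length
    if sten.center - half < -1e-12 or sten.center + half > branch.length + 1e-12:
        raise ConfigurationError("stenosis does not lie fully inside the branch")
    a0 = branch.area
    inside = np.abs(z_arr - sten.center) <= half
    prof = np.full_like(z_arr, a0)
    phase = 2.0 * np.pi * (z_arr - sten.center) / sten.length
    notch = a0 * (1.0 - 0.5 * sten.area_reduction * (1.0 + np.cos(phase)))
    prof = np.where(inside, notch, prof)
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(prof)
    return prof


@dataclass(frozen=True)
class BranchPath:
    """One inlet->outlet route through the bifurcation.

    The path coordinate starts at z = 0 at the LMCA inlet and runs
    continuously through the bifurcation plane into the branch and its outlet
    extension.  ``area(z)`` returns the *physical* lumen area, with the
    designed discontinuity at the bifurcation plane.
    """

    name: str  # "LAD" or "LCX"
    lmca: VesselSpec
    branch: VesselSpec
    outflow_fraction: float
    stenosis: StenosisSpec | None = None
    extension_length: float = 10e-3
    station_spacing: float = STATION_SPACING

    def __post_init__(self) -> None:
        if not (0 < self.outflow_fraction < 1):
            raise ConfigurationError("outflow_fraction must lie in (0, 1)")
        if self.extension_length < 0:
            raise ConfigurationError("extension_length must be >= 0")

    @property
    def bifurcation_z(self) -> float:
        return self.lmca.length

    @property
    def outlet_z(self) -> float:
        """Path coordinate of the nominal branch outlet (extension excluded)."""
        return self.lmca.length + self.branch.length

    @property
    def total_length(self) -> float:
        return self.outlet_z + self.extension_length

    def area(self, z):
        """Physical lumen area [m^2] at path coordinate ``z`` (scalar/array)."""
        z_arr = np.atleast_1d(np.asarray(z, dtype=float))
        if np.any(z_arr < -1e-12) or np.any(z_arr > self.total_length + 1e-12):
            raise DomainError(f"z outside path {self.name}")
        out = np.empty_like(z_arr)
        in_lmca = z_arr < self.bifurcation_z
        out[in_lmca] = self.lmca.area
        zb = np.clip(z_arr[~in_lmca] - self.bifurcation_z, 0.0,
                     self.branch.length + self.extension_length)
        if self.stenosis is None:
            out[~in_lmca] = self.branch.area
        else:
            ext_branch = replace(self.branch,
                                 length=self.branch.length + self.extension_length)
            out[~in_lmca] = stenosis_area_profile(zb, ext_branch, self.stenosis)
        if np.isscalar(z) or np.asarray(z).ndim == 0:
            return float(out[0])
        return out

    @property
    def stations(self) -> np.ndarray:
        """Path coordinates of the analysis stations (includes extension)."""
        n = int(math.floor(self.total_length / self.station_spacing + 1e-9)) + 1
        return self.station_spacing * np.arange(n)

    @property
    def station_excluded(self) -> np.ndarray:
        """True for stations inside the outlet extension (results neglected)."""
        return self.stations > self.outlet_z + 1e-9

    def branch_coordinate(self, z) -> np.ndarray:
        """Distance behind the bifurcation plane (negative inside the LMCA)."""
        return np.asarray(z, dtype=float) - self.bifurcation_z


@dataclass(frozen=True)
class BifurcationGeometry:
    """The complete two-path bifurcation model."""

    lmca: VesselSpec
    lad: VesselSpec
    lcx: VesselSpec
    stenosis: StenosisSpec
    branch_angle_deg: float = 80.0  # metadata only
    extension_length: float = 10e-3
    station_spacing: float = STATION_SPACING
    outflow_fraction_lad: float = 0.5

    def __post_init__(self) -> None:
        if self.extension_length < 0:
            raise ConfigurationError("extension_length must be >= 0")
        if not (0 < self.outflow_fraction_lad < 1):
            raise ConfigurationError("outflow_fraction_lad must lie in (0, 1)")

    @property
    def expansion_factor(self) -> float:
        """Total daughter area over mother area, 2 (r_b / r_LMCA)^2 by default."""
        return (self.lad.area + self.lcx.area) / self.lmca.area

    def path(self, branch: str, outflow_fraction: float | None = None) -> BranchPath:
        """Build the LAD (stenosed) or LCX (normal) path.

        ``outflow_fraction`` overrides the geometry default (scenarios carry
        their own flow splits).
        """
        key = branch.upper()
        if key == "LAD":
            f = self.outflow_fraction_lad if outflow_fraction is None else outflow_fraction
            return BranchPath("LAD", self.lmca, self.lad, f, self.stenosis,
                              self.extension_length, self.station_spacing)
        if key == "LCX":
            f = (1.0 - self.outflow_fraction_lad if outflow_fraction is None
                 else outflow_fraction)
            return BranchPath("LCX", self.lmca, self.lcx, f, None,
                              self.extension_length, self.station_spacing)
        raise DomainError(f"unknown branch {branch!r} (expected LAD or LCX)")

    @property
    def paths(self) -> tuple[BranchPath, BranchPath]:
        return (self.path("LAD"), self.path("LCX"))

    # -- plain-text serialization ------------------------------------------

    def to_config(self) -> dict:
        """Flat key-value representation (SI units)."""
        return {
            "lmca_radius_m": self.lmca.radius,
            "lmca_length_m": self.lmca.length,
            "lad_radius_m": self.lad.radius,
            "lad_length_m": self.lad.length,
            "lcx_radius_m": self.lcx.radius,
            "lcx_length_m": self.lcx.length,
            "stenosis_center_m": self.stenosis.center,
            "stenosis_length_m": self.stenosis.length,
            "stenosis_area_reduction": self.stenosis.area_reduction,
            "branch_angle_deg": self.branch_angle_deg,
            "extension_length_m": self.extension_length,
            "station_spacing_m": self.station_spacing,
        }

    def area_profile_csv(self, branch: str, n: int = 481) -> str:
        """Two-column CSV (z [m], A [m^2]) of a path's area profile."""
        p = self.path(branch)
        z = np.linspace(0.0, p.total_length, n)
        buf = io.StringIO()
        buf.write("z_m,area_m2\n")
        for zi, ai in zip(z, p.area(z)):
            buf.write(f"{zi:.6e},{ai:.6e}\n")
        return buf.getvalue()


def build_geometry(overrides: dict | None = None) -> BifurcationGeometry:
    """Construct the default bifurcation geometry, optionally overridden.

    Recognized override keys mirror :meth:`BifurcationGeometry.to_config`.
    The defaults reproduce the idealized geometry: the daughter-to-mother
    area expansion factor rounds to 1.25 and the LAD stenosis throat sits at
    path coordinate 35 mm (25 mm behind the bifurcation).
    """
    cfg = {
        "lmca_radius_m": 2.25e-3,
        "lmca_length_m": 10e-3,
        "lad_radius_m": 1.78e-3,
        "lad_length_m": 100e-3,
        "lcx_radius_m": 1.78e-3,
        "lcx_length_m": 100e-3,
        "stenosis_center_m": 25e-3,
        "stenosis_length_m": 10e-3,
        "stenosis_area_reduction": 0.80,
        "branch_angle_deg": 80.0,
        "extension_length_m": 10e-3,
        "station_spacing_m": STATION_SPACING,
    }
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ConfigurationError(f"unknown geometry overrides: {sorted(unknown)}")
        cfg.update(overrides)
    geo = BifurcationGeometry(
        lmca=VesselSpec("LMCA", cfg["lmca_radius_m"], cfg["lmca_length_m"]),
        lad=VesselSpec("LAD", cfg["lad_radius_m"], cfg["lad_length_m"]),
        lcx=VesselSpec("LCX", cfg["lcx_radius_m"], cfg["lcx_length_m"]),
        stenosis=StenosisSpec(cfg["stenosis_center_m"], cfg["stenosis_length_m"],
                              cfg["stenosis_area_reduction"]),
        branch_angle_deg=cfg["branch_angle_deg"],
        extension_length=cfg["extension_length_m"],
        station_spacing=cfg["station_spacing_m"],
    )
    # validate that the stenosis fits the (possibly overridden) branch
    stenosis_area_profile(0.0, geo.lad, geo.stenosis)
    return geo


def reynolds_number(density: float, velocity: float, diameter: float,
                    viscosity: float) -> float:
    """Re = rho v d / eta.  Diagnostic only; all arguments must be > 0."""
    for name, val in (("density", density), ("velocity", velocity),
                      ("diameter", diameter), ("viscosity", viscosity)):
        if not val > 0:
            raise DomainError(f"{name} must be > 0")
    return density * velocity * diameter / viscosity
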
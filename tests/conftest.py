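"""Shared fixtures: default geometry, scenarios, and small transport runs."""

import numpy as np
import pytest

from corodisp.geometry import build_geometry
from corodisp.synthflow import (GammaVariateAIF, constant_waveform,
                                make_waveform, scenario_table)
from corodisp.transport import (FluidProperties, TransportGrid, VelocityModel,
                                simulate_path, straight_tube_path)


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def scenarios():
    return {s.name: s for s in scenario_table()}


@pytest.fixture(scope="session")
def lv_aif():
    return GammaVariateAIF()


@pytest.fixture(scope="session")
def plug_tube_run():
    """Constant plug flow through a uniform 50 mm tube: pure advection."""
    tube = straight_tube_path(1.78e-3, 0.05)
    wf = constant_waveform(1.0, 0.2)
    aif = GammaVariateAIF().with_t0(2.0)
    grid = TransportGrid(n_radial=16, axial_spacing=1e-3, backend="auto")
    recs, quality = simulate_path(tube, wf, aif, grid=grid,
                                  model=VelocityModel("plug"), duration=40.0)
    return tube, aif, recs, quality


@pytest.fixture(scope="session")
def pulsatile_tube_run():
    """Pulsatile developing flow through a uniform 50 mm tube."""
    tube = straight_tube_path(1.78e-3, 0.05)
    wf = make_waveform(1.0, 0.15)
    aif = GammaVariateAIF().with_t0(2.0)
    grid = TransportGrid(n_radial=16, axial_spacing=1e-3, backend="auto")
    recs, quality = simulate_path(tube, wf, aif, grid=grid,
                                  model=VelocityModel("developing"),
                                  duration=40.0)
    return tube, aif, recs, quality
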
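"""Build the idealized coronary bifurcation and list the flow scenarios.

Prints the geometric constants (area expansion at the bifurcation, stenosis
throat) and the boundary-condition table of the eight simulated conditions.
"""

import numpy as np

from corodisp import build_geometry, scenario_table
from corodisp.synthflow import branch_inlet_mean_velocity

geo = build_geometry()
lad = geo.path("LAD")

print("LMCA radius          : %.2f mm" % (1e3 * geo.lmca.radius))
print("branch radius        : %.2f mm" % (1e3 * geo.lad.radius))
print("area expansion factor: %.4f (daughters/mother, ~1.25)"
      % geo.expansion_factor)
z = np.linspace(10e-3, 110e-3, 4001)
a = lad.area(z)
print("stenosis throat      : z = %.1f mm, %.0f%% area reduction"
      % (1e3 * z[np.argmin(a)], 100 * (1 - a.min() / geo.lad.area)))
print("analysis stations    : %d (2.5 mm apart, %d excluded in the outlet "
      "extension)" % (lad.stations.size, lad.station_excluded.sum()))

print("\nscenario                         split LAD/LCX  scale  v_in    "
      "v_LAD   period")
for sc in scenario_table():
    v_lad = branch_inlet_mean_velocity(sc, geo, "LAD")
    print("%-32s %.1f/%.1f      %.3f  %.3f   %.3f   %.1f s"
          % (sc.name, 100 * sc.outflow_fraction_lad,
             100 * sc.outflow_fraction_lcx, sc.scale_factor,
             sc.mean_inlet_velocity, v_lad, sc.period))
print("\nv_in is the LMCA mean inlet velocity [m/s]; v_LAD the continuity-"
      "derived\nmean velocity just behind the bifurcation in the stenosed "
      "branch.")
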
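"""Quantify the MBF error caused by neglecting bolus dispersion.

Generates tissue curves from inputs dispersed by exponential kernels of
increasing width, refits each with the undispersed LV input (the clinical
procedure), and prints the systematic MBF underestimation.  Runs in a few
seconds.
"""

import numpy as np

from corodisp import (ConcentrationRecord, FitSpec, GammaVariateAIF,
                      KineticParams, fit_mbf, generate_mctc,
                      lagged_normal_weights)
from corodisp.synthflow import aif_value, scenario_table

sc = next(s for s in scenario_table() if s.name == "fullAR_rest_pulsatile")
aif = GammaVariateAIF().with_t0(sc.bolus_arrival)
t = np.arange(0.0, sc.duration, 0.01)
lv = aif_value(t, aif)
params = KineticParams(mbf=1.0).for_state(sc.state)
het = lagged_normal_weights(params.rd_flow, params.n_paths)

print("true MBF = 1.0 mL/(g min); fits with the undispersed LV input:\n")
print("dispersion tau [s]   sigma2_VTF [s^2]   fitted MBF   E_MBF")
for tau in (0.0, 0.5, 1.0, 2.0, 4.0):
    if tau == 0.0:
        dispersed = lv
    else:
        k = np.exp(-t / tau) / tau
        k /= k.sum() * (t[1] - t[0])
        dispersed = np.convolve(lv, k)[:t.size] * (t[1] - t[0])
    rec = ConcentrationRecord("toi", 0.11, False, t, dispersed)
    tk, qk, _ = generate_mctc(rec, params, sc, heterogeneity=het)
    fit = fit_mbf(tk, qk, aif, FitSpec(), params, 1.0, heterogeneity=het)
    print("      %4.1f              %5.2f           %.3f      %+.1f%%"
          % (tau, tau**2, fit.fitted["mbf"], 100 * fit.e_mbf))
print("\nA wider vascular transport function (larger sigma2) flattens the "
      "tissue\ncurve; attributing that flattening to the kinetics alone "
      "drives the\nfitted flow down -- the dispersion error of quantitative "
      "perfusion MRI.")
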
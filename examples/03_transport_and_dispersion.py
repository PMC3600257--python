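"""Transport a bolus through a straight tube and quantify its dispersion.

Runs the reduced-order advection-diffusion solver for steady flow through
a 50 mm tube with a developing (plug -> Womersley) velocity profile and
prints how the mean vascular transit time (MVTT) and the VTF variance grow
with distance -- shear along the velocity profile stretches the bolus.
Takes a few seconds.
"""

from corodisp import (GammaVariateAIF, TransportGrid, VelocityModel,
                      dispersion_profile, simulate_path, straight_tube_path)
from corodisp.synthflow import make_waveform

tube = straight_tube_path(radius=1.78e-3, length=0.05)
waveform = make_waveform(period=1.0, mean=0.15, peak_to_mean=1.75)
aif = GammaVariateAIF().with_t0(3.0)

records, quality = simulate_path(
    tube, waveform, aif,
    grid=TransportGrid(n_radial=16, axial_spacing=1e-3),
    model=VelocityModel("developing"), duration=40.0)

print("solver: dt = %.2e s, %d steps, %d cells, mass drift %.2e"
      % (quality["dt"], quality["n_steps"], quality["n_cells"],
         quality["mass_drift_rel"]))

prof = dispersion_profile(records)
print("\n   z [mm]   MVTT [s]   sigma2_VTF [s^2]")
for z, mvtt, s2 in zip(prof.z[::4], prof.mvtt[::4], prof.sigma2[::4]):
    print("   %6.1f   %8.3f   %10.4f" % (1e3 * z, mvtt, s2))
print("\nMVTT tracks the bulk transit (z/u); sigma2 grows along the tube "
      "as the\nparabolic-ish profile shears the bolus (negligible radial "
      "diffusion at\nthis Peclet number).")
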
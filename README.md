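# corodisp

Contrast-agent bolus dispersion in a stenosed coronary bifurcation and its
impact on MRI-based quantification of myocardial blood flow.

## The problem

Quantitative first-pass perfusion MRI estimates myocardial blood flow
(MBF, mL/(g·min)) and the perfusion reserve (MPR = MBF_hyperemia /
MBF_rest) by fitting a tracer-kinetic model to tissue enhancement curves,
using an arterial input function (AIF) sampled in the left ventricle.
Between the LV and the myocardium the bolus disperses: along the coronary
arteries the AIF at the tissue of interest is the LV input convolved with
a vascular transport function (VTF),

    AIF_toi(t, z) = VTF(t, z) ⊗ AIF_LV(t),

and a VTF of nonzero width flattens the tissue curve.  A fit that ignores
this attributes the flattening to perfusion and systematically
underestimates MBF.  `corodisp` quantifies that bias in an idealized
left-coronary bifurcation (LMCA → LAD/LCX, 80% area stenosis in the LAD)
under eight flow conditions — {full, limited} autoregulation × {rest,
hyperemia} × {pulsatile, constant} — using a reduced-order pulsatile
advection–diffusion transport model in place of a 3D CFD solver.

Dispersion is measured without deconvolution through integral moments of
the recorded curves: the mean vascular transit time MVTT(z) and the VTF
variance

    σ²_VTF(z) = m₂/m₀|_z − m₂/m₀|₀ + (m₁/m₀|₀)² − (m₁/m₀|_z)²,

and the perfusion error by a generate-and-refit experiment with an
MMID4-style multipath model (20 heterogeneous pathways, arteriole +
two-region blood–tissue exchange units): tissue curves generated from the
dispersed branch-outlet AIF are refit with the undispersed LV input, giving
E_MBF = (MBF_fit − MBF_true)/MBF_true and E_MPR analogously.

See `docs/methods.md` for the models, numerics and limitations.

## Worked example

```bash
python examples/05_perfusion_error.py
```

```
true MBF = 1.0 mL/(g min); fits with the undispersed LV input:

dispersion tau [s]   sigma2_VTF [s^2]   fitted MBF   E_MBF
      0.0               0.00           1.000      +0.0%
      0.5               0.25           0.961      -3.9%
      1.0               1.00           0.940      -6.0%
      2.0               4.00           0.871      -12.9%
      4.0              16.00           0.740      -26.0%
```

With no dispersion the fit recovers the true flow exactly (the fitting
model equals the generating model); the wider the vascular transport
kernel, the stronger the MBF underestimation — the dispersion error of
quantitative perfusion MRI.

The other scripts in `examples/` walk through each capability: geometry
and the scenario table (`01`), waveform/bolus synthesis (`02`), bolus
transport and the σ²_VTF(z) profile (`03`), the multipath forward model
(`04`), and the full eight-scenario experiment (`06`, with `smoke`,
`desk` and `full` resolution profiles).  The same experiment is
available from the shell:

```bash
corodisp run --profile desk --out my_run     # dispersion + error tables
corodisp summarize my_run
corodisp make-fixtures --out fixtures        # synthetic inputs as CSV
```

A `desk`-profile run writes per-scenario dispersion profiles
(`dispersion_LAD.csv`, σ²_VTF and MVTT versus distance), tissue curves,
and combined `error_table.csv` / `mpr_table.csv` with one row per
scenario–branch fit; `summary.json` holds the headline flags (systematic
MBF underestimation, MPR overestimation, dispersion orderings, rank
correlation of E_MBF with outlet σ²_VTF).

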
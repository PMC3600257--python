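# Methods

`corodisp` estimates how dispersion of a contrast-agent bolus between the
left ventricle (LV) and the myocardium biases MRI-based myocardial blood
flow (MBF) and perfusion reserve (MPR) quantification, in an idealized
stenosed left-coronary bifurcation.  This note documents the models, the
numerical choices, and what the synthetic setting does and does not
represent.

## Geometry

The left main coronary artery (LMCA, radius 2.25 mm, length 10 mm) splits
into the LAD and LCX (radius 1.78 mm, length 100 mm each, branch angle 80
degrees kept as metadata).  Each branch carries a 10 mm outlet extension
whose stations are flagged `excluded` and never analyzed, so the outflow
boundary cannot contaminate the last analyzed station.  The total daughter
to mother area ratio is 2 (1.78/2.25)^2 = 1.2517, i.e. the cross-section
expands by ~1.25 at the bifurcation and the bulk velocity drops
accordingly.  The LAD carries a symmetric raised-cosine stenosis specified
by *area* reduction,

    A(z) = A0 [1 - f/2 (1 + cos(2 pi (z - z_c)/L))],

with f = 0.80, L = 10 mm, throat 25 mm behind the bifurcation.  Applying
the cosine to area rather than radius follows directly from the "80% area
reduction" specification; a radius-cosine profile would have a different
axial shape.  Analysis stations sit every 2.5 mm along the path
coordinate, which starts at the LMCA inlet (z = 0); outputs also carry the
distance behind the bifurcation.

Each inlet-to-outlet route is modeled as an axisymmetric streamtube: the
LMCA span is assigned the effective area f_out * A_LMCA (the fraction of
the mother vessel feeding that branch), so a single duct carries the
branch flow f_out * Q(t) with the correct bulk velocities everywhere and
exact flow continuity across the bifurcation plane.  The 3D bifurcation
flow (skewed profiles, secondary motion) is deliberately not represented.

## Inflow and bolus synthesis

The pulsatile LMCA inflow is a parametric diastolic-dominant template: a
small raised-cosine systolic lobe in the first 35% of the cycle, a larger
diastolic lobe after it, on a nonnegative baseline, normalized so the time
average and the peak are exact.  The default peak-to-mean ratio is 1.75,
chosen once so that peak stenosis-center Reynolds numbers land in the
physiological few-hundred-to-~1300 range across the scenarios; the true
ratio of a measured pattern is patient-dependent and is exposed as a
parameter.  Constant-flow variants use the time average of the
corresponding pulsatile pattern (zero temporal variance).

Eight scenarios = {full, limited} autoregulation x {rest, hyperemia} x
{pulsatile, constant}.  Full autoregulation keeps a 50/50 outflow split
(waveform scale 1.000 at rest -> 0.200 m/s mean; 2.300 at hyperemia ->
0.460 m/s, cycle shortened 1.0 -> 0.9 s).  Limited autoregulation shifts
flow away from the stenosed LAD: 45.3/54.7 with scale 0.915 (0.183 m/s) at
rest, 35.1/64.9 with scale 1.773 (0.355 m/s) at hyperemia, reproducing a
0.829 proximal velocity reduction at rest and velocity reserves of 1.5
(stenosed) / 2.3 (normal).

The LV bolus is the gamma-variate Y(t) = a (t-t0)^b exp(-c (t-t0)) with
a = 1.013e-3 (mass-fraction units), b = 2.142, c = 0.454 1/s.  t0 defaults
to the end of three cardiac cycles (3.0 s rest / 2.7 s hyperemia) and the
transport window is t0 + 50 s.  Viewed as an unnormalized shifted
Gamma(b+1, c) density, its mean transit is t0 + (b+1)/c = t0 + 6.921 s and
its variance 15.24 s^2 -- the closed-form oracle for the moment analysis.
Both generators are deterministic; the `seed` argument is reserved for an
optional measurement-noise add-on that is off by default.

## Reduced-order transport

Instead of a 3D Navier-Stokes solve, the velocity field is a prescribed
laminar kinematic closure satisfying continuity on rigid walls.  The
axisymmetric advection-diffusion equation for the contrast mass fraction
is integrated in (z, eta = r/R(z)) coordinates:

* `plug`, `parabolic`, `womersley` (analytic oscillatory pipe-flow
  profiles built from the Fourier harmonics of the inflow waveform at the
  local Womersley number alpha = R sqrt(n omega/nu) ~ 2.3 per harmonic at
  rest), and the default `developing`: a linear plug-to-Womersley blend
  over the entrance length L_e = 0.06 Re d, restarting at the path inlet,
  the bifurcation plane and the stenosis exit.  The restart is a crude
  surrogate for the jet/recirculation zone behind the throat and is the
  main fidelity gap of the stand-in.
* Radial shells of equal eta spacing carry per-shell axial volume fluxes;
  cross-shell radial fluxes are recovered from cell-wise continuity, so a
  uniform concentration field is preserved to machine precision and tracer
  mass is conserved exactly up to the recorded in/outflux (observed drift
  < 1e-10 relative).
* Numerics: conservative finite volume, van-Leer-limited MUSCL advection
  (explicit, positivity-based CFL bound with safety 0.5), implicit
  (backward-Euler/Thomas) radial molecular diffusion, explicit axial
  molecular diffusion (D = 1.5e-10 m^2/s; negligible but retained).
  Because the advection is explicit, the stable time step in the stenotic
  branch falls below 1 ms (down to ~4e-5 s at hyperemia); dt is
  auto-selected and capped at 10 ms.  The axial mesh is graded: up to 3x
  finer inside the stenosis and 1.3x near the bifurcation.  The velocity
  field is tabulated on 360 frames per cardiac cycle.  The stepper exists
  twice -- a numba fast path and a pure-numpy reference -- and the two are
  asserted identical in the tests.
* Blood is a Newtonian single-phase fluid (rho = 1050 kg/m^3, eta = 0.004
  kg/(m s)); the contrast agent is a passive scalar.

Station curves are cross-section averages.  Two conventions are
available: **area** weighting (default; an imaging voxel averages the
lumen) and **flux** weighting (the indicator-dilution convention).  The
distinction matters in sheared laminar flow: for steady Poiseuille flow
with no radial mixing the flux-weighted impulse response is the classic
residence-time density tau^2/(2 t^3), whereas the area-weighted kernel is
tau/(2 t^2), whose mean diverges logarithmically and is therefore
window-limited.  The laminar-RTD oracle test runs in flux mode; the
physiological pipeline runs in area mode.

At these Peclet numbers (R^2/D ~ 2e4 s, far above any transit time)
molecular diffusion cannot homogenize the cross-section during transit,
so computed sigma^2 values are sensitive to the radial discretization of
the slow near-wall shells (e.g. the LCX outlet variance grows from ~1.24
to ~1.99 s^2 between 16 and 24 shells at rest).  Comparisons across
scenarios at a fixed grid are consistent, and it is those comparisons --
not absolute variances -- that the package asserts.

## Dispersion analysis

The dispersed curve at a station is the inlet bolus convolved with the
vascular transport function (VTF); the VTF is never deconvolved.  Using
trapezoidal integral moments m_k = int t^k Y(t) dt over the recorded
window,

    MVTT(z)    = m1/m0 |_z - m1/m0 |_0
    sigma2(z)  = m2/m0 |_z - m2/m0 |_0 + (m1/m0 |_0)^2 - (m1/m0 |_z)^2,

which equals the VTF mean and variance by cumulant additivity.  The
infinite upper limits are realized as truncation at the end of the 50 s
transport window; on shortened test windows this produces small negative
variances near the inlet, which are clipped to zero and logged
(tolerance 1e-4 s^2).  At the full window the truncation bias is orders
of magnitude below the signal.

## Multipath tracer kinetics

The myocardial concentration-time curve (mCTC) is produced by a
multipath, 4-region whole-organ model in the MMID4 tradition: global
delay -> artery operator -> 20 parallel microcirculation pathways
(non-exchanging arteriole + axially distributed two-region blood-tissue
exchange unit) -> flux-weighted recombination -> venule and vein
operators.  The reported signal is the tracer content per gram summed
over all vascular and interstitial regions (an MR voxel contains both);
a region mask can restrict it.

* Pathway flows discretize a right-skewed lagged-normal density (mean 1,
  RD = 0.55, skew ratio tau/sigma_g = 1) into 20 equal-probability bins
  represented by conditional means, then affine-corrected to exact unit
  mean and exact RD.
* Vessel operators are unit-area lagged-normal kernels with mean transit
  V/F and SD = 0.48 V/F.  Their skew ratio defaults to 3, which keeps the
  Gaussian component more than 3 sigma above t = 0 so the causal
  truncation loses under 0.1% of kernel area at RD = 0.48; kernels
  degenerate to interpolated pure delays when SD < 2 dt.  The original
  MMID4 operator family is not uniquely documented; since the same model
  generates and refits the curves, the error estimates are well defined
  regardless of this choice.
* The BTEX unit solves dc_p/dt + (F L/V_p) dc_p/dx = (PS/V_p)(c_isf-c_p),
  dc_isf/dt = (PS/V_isf)(c_p-c_isf) by method of lines with 31 segments
  (RK4, substep-stabilized).  The segment chain adds numerical dispersion
  of relative magnitude 1/sqrt(31) ~ 0.18 to the intravascular spike; its
  moments are exact (mean transit V_p/F at PS = 0, (V_p+V_isf)/F in the
  flow-limited and long-window finite-PS cases, verified against closed
  forms and an independent stiff ODE solver).
* Parameters (mL/g, mL/(g min)): V_art = V_ven = 0.02, V_artl = 0.03 at
  rest / 0.06 at hyperemia, V_venl = 0.03, V_p = 0.04, V_isf = 0.35,
  PS = 1, delay = 0.  True MBF: 1 at rest; 2.3 at hyperemia (normal
  territory), 1.5 behind the stenosis under limited autoregulation.
* The kinetics grid is uniform at 25 ms; one sample per cardiac cycle
  over 44 cycles (phase 0, i.e. cycle start -- the acquisition phase is
  exposed as a parameter) feeds the fit, mirroring a clinical first-pass
  acquisition.

## Error estimation

mCTCs are generated from the *dispersed* branch-outlet input (last
non-excluded station, z = 110 mm; configurable) with the true parameters,
then refit with the *undispersed* LV gamma-variate.  The fit is bounded
least squares (scipy trust-region reflective, a bounded
Levenberg-Marquardt variant) over MBF [0, 7], PS [0.25, 8] mL/(g min),
delay [-1, 3] s, V_p [0.03, 0.09] mL/g, with unweighted SSE on the
44-point cycle lattice and initial values at the generation truth, as in
the clinical-style procedure; a deterministic multistart mode exists for
robustness studies.  E_MBF = (MBF_fit - MBF_true)/MBF_true and E_MPR
analogously from the hyperemia/rest ratio of fitted MBF.  Because fitter
and generator share the model, zero dispersion recovers the truth to
numerical precision, so any systematic error measures dispersion alone.

## Resolution profiles and problem sizes

* `full`: 0.5 mm base axial spacing, 24 radial shells, full 100 mm
  branches, t0 + 50 s window, 44 cycles.
* `desk`: 1.25 mm spacing, 16 shells, otherwise identical; the full
  eight-scenario experiment (16 transport solves + 16 bounded fits)
  completes in a few minutes on one core and is the configuration the
  test suite runs end to end.
* `smoke`: 20 mm branches (stenosis throat moved to 10 mm behind the
  bifurcation), 5 mm extensions, t0 + 20 s window, 10 cycles; it
  exercises every stage in seconds.  At this short window the moment
  truncation bias dominates the tiny true variances, so smoke runs
  exercise plumbing, not physics.

## What the reduced model reproduces, and what it does not

Reproduced (and asserted in the acceptance suite): the systematic MBF
underestimation in all 16 scenario-branch combinations; the systematic
MPR overestimation in all 8 rest/hyperemia pairs; larger stenotic-branch
dispersion under limited than under full autoregulation; pulsatile vs
constant outlet variance in the normal branch agreeing within a few
percent; negative rank correlation between E_MBF and outlet variance.

Not reproduced: effects whose mechanism is three-dimensional.  In
particular, the reduction of stenotic-branch dispersion by pulsatile flow
(attributed to pulse-driven displacement of laminar layers enhancing
transverse exchange at the stenosis) does not emerge from the laminar
kinematic closure -- here pulsatile flow shows ~2% *more* outlet variance
in the stenosed branch, stable under grid refinement.  Likewise the
closure makes the stenotic branch *less* dispersive than the normal one
under full autoregulation (fast throat transit plus the plug restart at
the stenosis exit), while jet/recirculation physics can make it more
dispersive.  No artificial transverse-mixing term was added to force
these orderings.  Wall compliance, non-Newtonian rheology, turbulence,
cardiac/respiratory motion and patient-specific geometry are out of
scope, as are Fermi-model quantification and semiquantitative indices.

Synthetic-data caveats: the inflow template and its peak-to-mean ratio
stand in for a measured phase-contrast pattern; hyperemic waveforms are
scaled copies of the rest shape, while real hyperemic and post-stenotic
patterns differ in shape; the pipeline is noise-free, so passing tests
bound the dispersion-induced bias only, not its interaction with
measurement noise.
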
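"""Finite-volume machinery behind :mod:`corodisp.transport`.

The solver discretizes one branch path as an axisymmetric duct in
(z, eta) coordinates, eta = r / R(z) in [0, 1]:

* axial cells on a graded mesh (refined inside the stenosis and around the
  bifurcation plane),
* ``n_radial`` annular shells of equal eta spacing,
* per-shell axial volume fluxes prescribed by the kinematic velocity model
  (plug / parabolic / Womersley / developing blend), periodic in time and
  tabulated once per run on a frame lattice spanning one cardiac cycle,
* cross-shell radial volume fluxes recovered from cell-wise continuity, so
  that a spatially constant concentration field is preserved exactly,
* explicit MUSCL (van-Leer limited) advection, explicit axial molecular
  diffusion, implicit (backward-Euler, Thomas) radial molecular diffusion.

Two interchangeable steppers exist: a pure-numpy reference and a numba
njit fast path; they implement the same update and are compared in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

try:
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency normally
    numba = None
    HAVE_NUMBA = False

# ---------------------------------------------------------------------------
# axial mesh
# ---------------------------------------------------------------------------

def _graded(z0: float, z1: float, h_start: float, h_end: float) -> np.ndarray:
    """Faces on [z0, z1] with spacing varying linearly h_start -> h_end."""
    span = z1 - z0
    if span <= 0:
        return np.array([z0, z1])[:0]
    n = max(1, int(math.ceil(2.0 * span / (h_start + h_end))))
    h = np.linspace(h_start, h_end, n)
    h *= span / h.sum()
    return z0 + np.concatenate(([0.0], np.cumsum(h)))


def build_axial_faces(path, base_spacing: float, stenosis_refinement: float,
                      bifurcation_refinement: float,
                      bif_band: float = 5e-3) -> np.ndarray:
    """Graded axial face positions for one path."""
    h0 = base_spacing
    bif = path.bifurcation_z
    end = path.total_length
    rb = max(1.0, bifurcation_refinement)
    rs = max(1.0, stenosis_refinement)
    band = min(bif_band, 0.5 * bif, 0.25 * (end - bif))
    segs: list[tuple[float, float, float, float]] = []
    if bif - band > 1e-12:
        segs.append((0.0, bif - band, h0, h0))
    segs.append((max(0.0, bif - band), bif, h0, h0 / rb))
    segs.append((bif, bif + band, h0 / rb, h0))
    z_resume = bif + band
    if path.stenosis is not None:
        ss = bif + path.stenosis.center - 0.5 * path.stenosis.length
        se = bif + path.stenosis.center + 0.5 * path.stenosis.length
        sc = bif + path.stenosis.center
        ss = max(ss, z_resume)
        if ss > z_resume + 1e-12:
            segs.append((z_resume, ss, h0, h0))
        segs.append((ss, sc, h0, h0 / rs))
        segs.append((sc, se, h0 / rs, h0))
        z_resume = se
    if end > z_resume + 1e-12:
        segs.append((z_resume, end, h0, h0))
    faces = [np.array([0.0])]
    for z0, z1, hs, he in segs:
        part = _graded(z0, z1, hs, he)
        if part.size:
            faces.append(part[1:])
    zf = np.concatenate(faces)
    return np.unique(np.round(zf, 12))


# ---------------------------------------------------------------------------
# velocity profile shapes
# ---------------------------------------------------------------------------

def womersley_shape(eta: np.ndarray, alpha: float) -> np.ndarray:
    """Complex unit-mean oscillatory pipe-flow profile shape.

    S(eta) = [1 - J0(l eta)/J0(l)] / [1 - 2 J1(l)/(l J0(l))] with
    l = i^{3/2} alpha; the cross-section (area) average of S is 1, so a
    harmonic with mean-velocity amplitude u_hat has velocity u_hat * S.
    Alpha -> 0 recovers the parabolic profile 2 (1 - eta^2).
    """
    if alpha < 1e-3:
        return 2.0 * (1.0 - np.asarray(eta) ** 2) + 0j
    lam = 1j ** 1.5 * alpha
    j0l = jv(0, lam)
    denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0l)
    return (1.0 - jv(0, lam * np.asarray(eta)) / j0l) / denom


def parabolic_shell_means(eta_if: np.ndarray) -> np.ndarray:
    """Area-weighted shell means of the Poiseuille shape 2 (1 - eta^2)."""
    lo, hi = eta_if[:-1], eta_if[1:]
    return 2.0 - (lo**2 + hi**2)


def shell_means_of_shape(shape_fn, eta_if: np.ndarray, nsub: int = 6) -> np.ndarray:
    """Area-weighted means of an arbitrary profile shape over each shell."""
    out = np.empty(eta_if.size - 1, dtype=complex)
    for i in range(eta_if.size - 1):
        lo, hi = eta_if[i], eta_if[i + 1]
        e = np.linspace(lo, hi, nsub)
        vals = shape_fn(e) * e
        out[i] = 2.0 * np.trapezoid(vals, e) / (hi**2 - lo**2)
    return out


# ---------------------------------------------------------------------------
# tabulated run setup
# ---------------------------------------------------------------------------

@dataclass
class SolverTables:
    """Everything the stepper needs, precomputed."""

    zf: np.ndarray          # axial faces [m], (nzf,)
    zc: np.ndarray          # cell centers, (nz,)
    dz: np.ndarray          # cell widths, (nz,)
    a_c: np.ndarray         # effective duct area at centers, (nz,)
    a_shell: np.ndarray     # shell area fractions, (nr,)
    vol: np.ndarray         # cell volumes, (nr, nz)
    q: np.ndarray           # per-frame per-shell axial face fluxes, (nf, nr, nzf)
    w: np.ndarray           # per-frame radial interface fluxes, (nf, nr-1, nz)
    period: float
    dt: float
    n_steps: int
    # Thomas factorization for implicit radial diffusion
    rad_low: np.ndarray     # (nr, nz)
    rad_cp: np.ndarray      # (nr, nz)
    rad_den: np.ndarray     # (nr, nz)
    ax_diff: np.ndarray     # axial diffusive conductances per face, (nr, nzf)


def build_tables(path, waveform, fluid, base_spacing: float,
                 stenosis_refinement: float, bifurcation_refinement: float,
                 n_radial: int, profile_kind: str, n_harmonics: int,
                 entrance_coefficient: float, n_frames: int,
                 duration: float, dt_user: float | None, dt_max: float,
                 cfl: float) -> SolverTables:
    zf = build_axial_faces(path, base_spacing, stenosis_refinement,
                           bifurcation_refinement)
    zc = 0.5 * (zf[:-1] + zf[1:])
    dz = np.diff(zf)
    nz = zc.size
    bif = path.bifurcation_z
    f_out = path.outflow_fraction

    def area_eff(z: np.ndarray, downstream_at_bif: bool) -> np.ndarray:
        """Effective streamtube area: f * A_LMCA before the bifurcation."""
        z = np.asarray(z, dtype=float)
        phys = path.area(np.clip(z, 0.0, path.total_length))
        phys = np.atleast_1d(np.asarray(phys, dtype=float))
        if downstream_at_bif:
            in_lmca = z < bif - 1e-12
        else:
            in_lmca = z < bif + 1e-12
        return np.where(in_lmca, f_out * path.lmca.area, phys)

    A_f = area_eff(zf, downstream_at_bif=True)
    A_c = area_eff(zc, downstream_at_bif=False)
    R_f = np.sqrt(A_f / math.pi)
    R_c = np.sqrt(A_c / math.pi)

    nr = n_radial
    eta_if = np.arange(nr + 1) / nr
    a_shell = np.diff(eta_if**2)

    # inlet area of the streamtube; Q(t) = A_in * u_in(t)
    A_in = f_out * path.lmca.area

    u_hat, omega = waveform.harmonics(n_harmonics)
    if waveform.is_constant:
        u_hat = u_hat[:1]
    nh = u_hat.size

    # --- blended unit-mean shell shapes per harmonic at every face ---------
    nu = fluid.viscosity / fluid.density
    W = np.ones((nh, nr, zf.size), dtype=complex)
    if profile_kind != "plug":
        par = parabolic_shell_means(eta_if).astype(complex)
        # steady-harmonic developed shape is parabolic; oscillatory harmonics
        # use the Womersley solution at the local radius
        shapes = np.empty((nh, nr, zf.size), dtype=complex)
        shapes[0] = par[:, None]
        if nh > 1:
            r_round = np.round(R_f, 9)
            uniq = np.unique(r_round)
            cache: dict[tuple[int, float], np.ndarray] = {}
            for n in range(1, nh):
                for rv in uniq:
                    alpha = rv * math.sqrt(n * omega / nu)
                    cache[(n, rv)] = shell_means_of_shape(
                        lambda e: womersley_shape(e, alpha), eta_if)
                for j, rv in enumerate(r_round):
                    shapes[n, :, j] = cache[(n, rv)]
        if profile_kind == "parabolic":
            W[:] = par[:, None][None, :, :]
        elif profile_kind == "womersley":
            W[:] = shapes
        elif profile_kind == "developing":
            beta = _development_fraction(path, waveform, fluid, zf,
                                         entrance_coefficient, A_f, R_f)
            W[:] = (1.0 - beta)[None, None, :] + beta[None, None, :] * shapes
        else:
            raise ValueError(f"unknown profile kind {profile_kind!r}")

    # --- per-frame velocity/flux tables ------------------------------------
    nf = 1 if waveform.is_constant else n_frames
    t_frames = np.arange(nf) * (waveform.period / nf)
    E = np.empty((nh, nf), dtype=complex)
    for n in range(nh):
        E[n] = u_hat[n] * np.exp(1j * n * omega * t_frames)
    u_face = np.einsum("nf,nij->fij", E, W).real
    u_face *= (A_in / A_f)[None, None, :]
    # enforce exact discrete continuity: shell-area mean == bulk velocity
    target = (A_in / A_f)[None, :] * waveform.value(t_frames)[:, None]
    current = np.einsum("i,fij->fj", a_shell, u_face)
    ratio = np.where(np.abs(current) > 1e-14, target / np.where(
        np.abs(current) > 1e-14, current, 1.0), 1.0)
    u_face *= ratio[:, None, :]

    q = u_face * (a_shell[:, None] * A_f[None, :])[None, :, :]
    # radial interface volume fluxes from cell continuity (positive outward)
    resid = q[:, :, :-1] - q[:, :, 1:]
    w = np.cumsum(resid, axis=1)[:, :-1, :]

    vol = a_shell[:, None] * A_c[None, :] * dz[None, :]

    # --- time step from a positivity (CFL-like) bound -----------------------
    out_flux = (np.maximum(q[:, :, 1:], 0.0) + np.maximum(-q[:, :, :-1], 0.0))
    w_pad = np.zeros((nf, nr + 1, nz))
    w_pad[:, 1:nr, :] = w
    out_flux = out_flux + np.maximum(w_pad[:, 1:, :], 0.0) \
        + np.maximum(-w_pad[:, :-1, :], 0.0)
    with np.errstate(divide="ignore"):
        dt_bound = np.min(np.where(out_flux > 0, vol[None] / out_flux, np.inf))
    dt = min(cfl * float(dt_bound), dt_max)
    if dt_user is not None:
        dt = min(dt_user, dt)
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("could not determine a stable time step")
    n_steps = int(math.ceil(duration / dt))

    # --- implicit radial diffusion (backward Euler, Thomas factorization) --
    D = fluid.diffusion
    g = np.zeros((nr + 1, nz))
    deta = 1.0 / nr
    for s in range(1, nr):
        g[s] = 2.0 * D * eta_if[s] / (R_c**2 * deta)
    low = np.zeros((nr, nz))
    up = np.zeros((nr, nz))
    diag = np.ones((nr, nz))
    for i in range(nr):
        gl = g[i] / a_shell[i]
        gu = g[i + 1] / a_shell[i]
        low[i] = -dt * gl
        up[i] = -dt * gu
        diag[i] = 1.0 + dt * (gl + gu)
    cp = np.zeros((nr, nz))
    den = np.zeros((nr, nz))
    den[0] = diag[0]
    cp[0] = up[0] / den[0]
    for i in range(1, nr):
        den[i] = diag[i] - low[i] * cp[i - 1]
        cp[i] = up[i] / den[i]

    # axial diffusive conductances D * A_face * a_i / dz_centerdist
    dzc = np.empty(zf.size)
    dzc[1:-1] = zc[1:] - zc[:-1]
    dzc[0] = dzc[-1] = np.inf  # no diffusive flux through inlet/outlet
    ax_diff = D * (a_shell[:, None] * A_f[None, :]) / dzc[None, :]

    return SolverTables(zf=zf, zc=zc, dz=dz, a_c=A_c, a_shell=a_shell,
                        vol=vol, q=q, w=w, period=waveform.period, dt=dt,
                        n_steps=n_steps, rad_low=low, rad_cp=cp, rad_den=den,
                        ax_diff=ax_diff)


def _development_fraction(path, waveform, fluid, zf, coeff, A_f, R_f):
    """Linear plug->developed blend factor beta(z) in [0, 1].

    The profile development restarts at the inlet, the bifurcation plane and
    the stenosis exit; the entrance length is L_e = coeff * Re * d from the
    local time-mean bulk velocity and diameter just downstream of each reset.
    """
    resets = [0.0, path.bifurcation_z]
    if path.stenosis is not None:
        resets.append(path.bifurcation_z + path.stenosis.center
                      + 0.5 * path.stenosis.length)
    resets = sorted(r for r in resets if r < path.total_length)
    beta = np.zeros(zf.size)
    A_in = path.outflow_fraction * path.lmca.area
    for k, z0 in enumerate(resets):
        z1 = resets[k + 1] if k + 1 < len(resets) else np.inf
        sel = (zf >= z0 - 1e-12) & (zf < z1)
        if not np.any(sel):
            continue
        j0 = np.argmax(sel)
        u_mean = A_in * waveform.mean / A_f[j0]
        d = 2.0 * R_f[j0]
        re = fluid.density * u_mean * d / fluid.viscosity
        le = max(coeff * re * d, 1e-6)
        beta[sel] = np.clip((zf[sel] - z0) / le, 0.0, 1.0)
    return beta


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

def run_numpy(tab: SolverTables, y_in_steps: np.ndarray, record_every: int,
              station_cells: np.ndarray,
              rec_w: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pure-numpy reference stepper.

    Returns (record_times, records[n_rec, n_stations_interior], balance).
    ``station_cells`` holds interior cell indices; the caller handles the
    z = 0 inlet reference separately.  ``rec_w`` (nf, nr, n_stations) are
    per-frame station averaging weights (area or flux weighting).
    """
    nf, nr, nzf = tab.q.shape
    nz = nzf - 1
    Y = np.zeros((nr, nz))
    n_rec = tab.n_steps // record_every + 2
    rec = np.zeros((n_rec, station_cells.size))
    rec_t = np.zeros(n_rec)
    irec = 0
    m_in = 0.0
    m_out = 0.0
    dt = tab.dt
    for step in range(tab.n_steps):
        t = step * dt
        frame = int((t % tab.period) / tab.period * nf) % nf
        if step % record_every == 0:
            rec_t[irec] = t
            rec[irec] = (rec_w[frame] * Y[:, station_cells]).sum(axis=0)
            irec += 1
        qf = tab.q[frame]
        wf = tab.w[frame]
        y_in = y_in_steps[step]

        Yp = np.empty((nr, nz + 2))
        Yp[:, 0] = y_in
        Yp[:, 1:-1] = Y
        Yp[:, -1] = Y[:, -1]
        # MUSCL face values (uniform-grid limiter formula)
        pos = qf >= 0.0
        idx_up = np.where(pos, np.arange(nzf)[None, :], np.arange(nzf)[None, :] + 1)
        idx_dn = np.where(pos, np.arange(nzf)[None, :] + 1, np.arange(nzf)[None, :])
        idx_uu = np.where(pos, np.maximum(idx_up - 1, 0),
                          np.minimum(idx_up + 1, nz + 1))
        rows = np.arange(nr)[:, None]
        y_up = Yp[rows, idx_up]
        y_dn = Yp[rows, idx_dn]
        y_uu = Yp[rows, idx_uu]
        # van-Leer limited correction in division-safe harmonic form:
        # 0.5 * phi(r) * (y_dn - y_up) == s*d/(s+d) when s*d > 0 else 0
        s = y_up - y_uu
        d = y_dn - y_up
        prod = s * d
        corr = np.where(prod > 0.0, prod / np.where(prod > 0.0, s + d, 1.0), 0.0)
        y_face = y_up + corr
        y_face[:, 0] = np.where(qf[:, 0] >= 0, y_in, Y[:, 0])
        y_face[:, -1] = np.where(qf[:, -1] >= 0, Y[:, -1], y_in * 0.0)
        F = qf * y_face
        m_in += dt * F[:, 0].sum()
        m_out += dt * F[:, -1].sum()
        dY = (F[:, :-1] - F[:, 1:])
        # radial advective exchange (upwind)
        yu = np.where(wf >= 0, Y[:-1, :], Y[1:, :])
        G = wf * yu
        dY[:-1] -= G
        dY[1:] += G
        # axial molecular diffusion (explicit); Fd at interior faces
        Fd = tab.ax_diff[:, 1:-1] * (Y[:, 1:] - Y[:, :-1])
        dY[:, :-1] += Fd
        dY[:, 1:] -= Fd
        Y = Y + dt * dY / tab.vol
        # implicit radial molecular diffusion (Thomas back-substitution)
        dp = np.empty_like(Y)
        dp[0] = Y[0] / tab.rad_den[0]
        for i in range(1, nr):
            dp[i] = (Y[i] - tab.rad_low[i] * dp[i - 1]) / tab.rad_den[i]
        Y[nr - 1] = dp[nr - 1]
        for i in range(nr - 2, -1, -1):
            Y[i] = dp[i] - tab.rad_cp[i] * Y[i + 1]
        if step % 2000 == 0 and not np.isfinite(Y[nr // 2, nz // 2]):
            raise FloatingPointError("solver blow-up (NaN detected)")
    if irec < n_rec:
        t = tab.n_steps * dt
        frame = int((t % tab.period) / tab.period * nf) % nf
        rec_t[irec] = t
        rec[irec] = (rec_w[frame] * Y[:, station_cells]).sum(axis=0)
        irec += 1
    mass_final = float((Y * tab.vol).sum())
    balance = {"mass_in": m_in, "mass_out": m_out, "mass_final": mass_final,
               "drift": m_in - m_out - mass_final}
    return rec_t[:irec], rec[:irec], balance


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _step_loop_numba(q, w, vol, ax_diff, rad_low, rad_cp, rad_den,
                         y_in_steps, dt, period, n_steps, record_every,
                         station_cells, rec_w, rec_t, rec):  # pragma: no cover
        nf, nr, nzf = q.shape
        nz = nzf - 1
        Y = np.zeros((nr, nz))
        Ynew = np.zeros((nr, nz))
        yface = np.zeros((nr, nzf))
        dp = np.zeros(nr)
        irec = 0
        m_in = 0.0
        m_out = 0.0
        status = 0
        for step in range(n_steps):
            t = step * dt
            frame = int((t % period) / period * nf) % nf
            if step % record_every == 0:
                rec_t[irec] = t
                for s in range(station_cells.size):
                    acc = 0.0
                    jc = station_cells[s]
                    for i in range(nr):
                        acc += rec_w[frame, i, s] * Y[i, jc]
                    rec[irec, s] = acc
                irec += 1
            y_in = y_in_steps[step]
            # face values with van-Leer limiter
            for i in range(nr):
                for j in range(nzf):
                    qv = q[frame, i, j]
                    if j == 0:
                        yface[i, j] = y_in if qv >= 0.0 else Y[i, 0]
                        continue
                    if j == nz:
                        yface[i, j] = Y[i, nz - 1] if qv >= 0.0 else 0.0
                        continue
                    if qv >= 0.0:
                        yu = Y[i, j - 1]
                        yd = Y[i, j]
                        yuu = Y[i, j - 2] if j >= 2 else y_in
                    else:
                        yu = Y[i, j]
                        yd = Y[i, j - 1]
                        yuu = Y[i, j + 1] if j + 1 <= nz - 1 else Y[i, nz - 1]
                    # division-safe van-Leer correction (harmonic form)
                    sv = yu - yuu
                    dv = yd - yu
                    pv = sv * dv
                    corr = pv / (sv + dv) if pv > 0.0 else 0.0
                    yface[i, j] = yu + corr
            for i in range(nr):
                m_in += dt * q[frame, i, 0] * yface[i, 0]
                m_out += dt * q[frame, i, nz] * yface[i, nz]
            for i in range(nr):
                for j in range(nz):
                    d = q[frame, i, j] * yface[i, j] \
                        - q[frame, i, j + 1] * yface[i, j + 1]
                    # radial advective exchange
                    if i < nr - 1:
                        wv = w[frame, i, j]
                        yu = Y[i, j] if wv >= 0.0 else Y[i + 1, j]
                        d -= wv * yu
                    if i > 0:
                        wv = w[frame, i - 1, j]
                        yu = Y[i - 1, j] if wv >= 0.0 else Y[i, j]
                        d += wv * yu
                    # axial molecular diffusion
                    if j < nz - 1:
                        d += ax_diff[i, j + 1] * (Y[i, j + 1] - Y[i, j])
                    if j > 0:
                        d -= ax_diff[i, j] * (Y[i, j] - Y[i, j - 1])
                    Ynew[i, j] = Y[i, j] + dt * d / vol[i, j]
            # implicit radial diffusion, Thomas per column
            for j in range(nz):
                dp[0] = Ynew[0, j] / rad_den[0, j]
                for i in range(1, nr):
                    dp[i] = (Ynew[i, j] - rad_low[i, j] * dp[i - 1]) \
                        / rad_den[i, j]
                Y[nr - 1, j] = dp[nr - 1]
                for i in range(nr - 2, -1, -1):
                    Y[i, j] = dp[i] - rad_cp[i, j] * Y[i + 1, j]
            if step % 2000 == 0:
                if not np.isfinite(Y[nr // 2, nz // 2]):
                    status = 1
                    break
        if status == 0 and irec < rec_t.size:
            t = n_steps * dt
            frame = int((t % period) / period * nf) % nf
            rec_t[irec] = t
            for s in range(station_cells.size):
                acc = 0.0
                jc = station_cells[s]
                for i in range(nr):
                    acc += rec_w[frame, i, s] * Y[i, jc]
                rec[irec, s] = acc
            irec += 1
        mass_final = 0.0
        for i in range(nr):
            for j in range(Y.shape[1]):
                mass_final += Y[i, j] * vol[i, j]
        return status, irec, m_in, m_out, mass_final


def run_numba(tab: SolverTables, y_in_steps: np.ndarray, record_every: int,
              station_cells: np.ndarray, rec_w: np.ndarray):
    """Numba fast path with the same contract as :func:`run_numpy`."""
    if not HAVE_NUMBA:  # pragma: no cover
        return run_numpy(tab, y_in_steps, record_every, station_cells, rec_w)
    n_rec = tab.n_steps // record_every + 2
    rec = np.zeros((n_rec, station_cells.size))
    rec_t = np.zeros(n_rec)
    status, irec, m_in, m_out, mass_final = _step_loop_numba(
        tab.q, tab.w, tab.vol, tab.ax_diff, tab.rad_low, tab.rad_cp,
        tab.rad_den, y_in_steps, tab.dt, tab.period, tab.n_steps,
        record_every, station_cells.astype(np.int64),
        np.ascontiguousarray(rec_w), rec_t, rec)
    if status != 0:
        raise FloatingPointError("solver blow-up (NaN detected)")
    balance = {"mass_in": m_in, "mass_out": m_out, "mass_final": mass_final,
               "drift": m_in - m_out - mass_final}
    return rec_t[:irec], rec[:irec], balance
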
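"""Numba kernels: counter-based RNG, RKF45 cell integrators, engine loop.

Everything here operates on plain float64/int64 arrays so the whole
simulation loop compiles to machine code.  Public, documented wrappers
live in :mod:`gliasim.core_models` and :mod:`gliasim.engine`.

Random numbers are counter-based (splitmix64 of ``(seed, cell, kind,
step, draw)``): every cell has its own logical stream for each purpose,
and results are independent of evaluation order, thread count, and of
which recorders are attached.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# --- astrocyte parameter column layout (matches AstrocyteParams.as_array) ---
A_R_ER, A_V_IP3R, A_KD1, A_KD2, A_KD_ACT, A_KD_INH, A_K_IP3R = 0, 1, 2, 3, 4, 5, 6
A_V_SERCA, A_KM_SERCA, A_V_L, A_CA_TOT, A_IP3_0, A_TAU_IP3 = 7, 8, 9, 10, 11, 12
A_DELTA_IP3, A_SIC_TH, A_SIC_SCALE, A_NOISE_SD, A_SIC_CONST = 13, 14, 15, 16, 17

# --- neuron parameter column layout (matches AdexParams.as_array) ---
N_CM, N_GL, N_EL, N_DT, N_VT, N_A, N_TAUW, N_B = 0, 1, 2, 3, 4, 5, 6, 7
N_VRESET, N_VPEAK, N_TREF, N_EEXC, N_EINH, N_TAUE, N_TAUI = 8, 9, 10, 11, 12, 13, 14

_E = math.e
_MAX_EXP_ARG = 10.0  # clamp of the AdEx exponential; v then races to V_peak

_U0 = np.uint64(0x9E3779B97F4A7C15)
_U1 = np.uint64(0xBF58476D1CE4E5B9)
_U2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = z + _U0
    z = (z ^ (z >> _S30)) * _U1
    z = (z ^ (z >> _S27)) * _U2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _rand_u(seed, cell, kind, step, idx):
    """Uniform draw in (0, 1], keyed by (seed, cell, kind, step, idx)."""
    h = _splitmix64(np.uint64(seed))
    h = _splitmix64(h ^ np.uint64(cell))
    h = _splitmix64(h ^ (np.uint64(kind) + np.uint64(0xD1B54A32D192ED03)))
    h = _splitmix64(h ^ (np.uint64(step) * np.uint64(256) + np.uint64(idx)))
    return (float(h >> _S11) + 1.0) * _INV53


@njit(cache=True, inline="always")
def _rand_normal(seed, cell, kind, step):
    u1 = _rand_u(seed, cell, kind, step, 0)
    u2 = _rand_u(seed, cell, kind, step, 1)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(cache=True, inline="always")
def _rand_poisson(lam, seed, cell, kind, step):
    """Knuth Poisson sampler; intended for small per-step means."""
    if lam <= 0.0:
        return 0
    limit = math.exp(-lam)
    k = 0
    p = 1.0
    idx = 8
    while True:
        p *= _rand_u(seed, cell, kind, step, idx)
        idx += 1
        if p <= limit:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Astrocyte dynamics
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def astro_rhs(ca, ip3, h, p):
    """Smooth part of the Li-Rinzel system; returns (dca, dh, dip3)."""
    ca_er = (p[A_CA_TOT] - ca) / p[A_R_ER]
    m_inf = ip3 / (ip3 + p[A_KD1])
    n_inf = ca / (ca + p[A_KD_ACT])
    gate = m_inf * n_inf * h
    j_channel = p[A_R_ER] * p[A_V_IP3R] * gate * gate * gate * (ca_er - ca)
    j_pump = p[A_V_SERCA] * ca * ca / (p[A_KM_SERCA] ** 2 + ca * ca)
    j_leak = p[A_R_ER] * p[A_V_L] * (ca_er - ca)
    alpha_h = p[A_K_IP3R] * p[A_KD_INH] * (ip3 + p[A_KD1]) / (ip3 + p[A_KD2])
    beta_h = p[A_K_IP3R] * ca
    dca = j_channel - j_pump + j_leak
    dh = alpha_h * (1.0 - h) - beta_h * h
    dip3 = (p[A_IP3_0] - ip3) / p[A_TAU_IP3]
    return dca, dh, dip3


@njit(cache=True, inline="always")
def sic_from_ca(ca, sic_th_nM, sic_scale):
    """F_SIC: a_SIC * ln((ca[nM] - theta_SIC)/nM) above theta_SIC + 1 nM."""
    c_scaled = ca * 1000.0 - sic_th_nM
    if c_scaled > 1.0:
        return sic_scale * math.log(c_scaled)
    return 0.0


@njit(cache=True)
def astro_integrate(ca, ip3, h, p, dt, tol):
    """Adaptive RKF45 of the Li-Rinzel system over one grid step.

    Substeps are bounded above by ``dt``.  Returns (ca, ip3, h, ok).
    """
    t = 0.0
    h_try = dt
    while t < dt - 1e-12:
        if h_try > dt - t:
            h_try = dt - t
        k1c, k1h, k1i = astro_rhs(ca, ip3, h, p)
        k2c, k2h, k2i = astro_rhs(
            ca + h_try * 0.25 * k1c, ip3 + h_try * 0.25 * k1i,
            h + h_try * 0.25 * k1h, p)
        k3c, k3h, k3i = astro_rhs(
            ca + h_try * (3.0 / 32.0 * k1c + 9.0 / 32.0 * k2c),
            ip3 + h_try * (3.0 / 32.0 * k1i + 9.0 / 32.0 * k2i),
            h + h_try * (3.0 / 32.0 * k1h + 9.0 / 32.0 * k2h), p)
        k4c, k4h, k4i = astro_rhs(
            ca + h_try * (1932.0 / 2197.0 * k1c - 7200.0 / 2197.0 * k2c + 7296.0 / 2197.0 * k3c),
            ip3 + h_try * (1932.0 / 2197.0 * k1i - 7200.0 / 2197.0 * k2i + 7296.0 / 2197.0 * k3i),
            h + h_try * (1932.0 / 2197.0 * k1h - 7200.0 / 2197.0 * k2h + 7296.0 / 2197.0 * k3h), p)
        k5c, k5h, k5i = astro_rhs(
            ca + h_try * (439.0 / 216.0 * k1c - 8.0 * k2c + 3680.0 / 513.0 * k3c - 845.0 / 4104.0 * k4c),
            ip3 + h_try * (439.0 / 216.0 * k1i - 8.0 * k2i + 3680.0 / 513.0 * k3i - 845.0 / 4104.0 * k4i),
            h + h_try * (439.0 / 216.0 * k1h - 8.0 * k2h + 3680.0 / 513.0 * k3h - 845.0 / 4104.0 * k4h), p)
        k6c, k6h, k6i = astro_rhs(
            ca + h_try * (-8.0 / 27.0 * k1c + 2.0 * k2c - 3544.0 / 2565.0 * k3c + 1859.0 / 4104.0 * k4c - 11.0 / 40.0 * k5c),
            ip3 + h_try * (-8.0 / 27.0 * k1i + 2.0 * k2i - 3544.0 / 2565.0 * k3i + 1859.0 / 4104.0 * k4i - 11.0 / 40.0 * k5i),
            h + h_try * (-8.0 / 27.0 * k1h + 2.0 * k2h - 3544.0 / 2565.0 * k3h + 1859.0 / 4104.0 * k4h - 11.0 / 40.0 * k5h), p)
        c5 = ca + h_try * (16.0 / 135.0 * k1c + 6656.0 / 12825.0 * k3c + 28561.0 / 56430.0 * k4c - 9.0 / 50.0 * k5c + 2.0 / 55.0 * k6c)
        i5 = ip3 + h_try * (16.0 / 135.0 * k1i + 6656.0 / 12825.0 * k3i + 28561.0 / 56430.0 * k4i - 9.0 / 50.0 * k5i + 2.0 / 55.0 * k6i)
        h5 = h + h_try * (16.0 / 135.0 * k1h + 6656.0 / 12825.0 * k3h + 28561.0 / 56430.0 * k4h - 9.0 / 50.0 * k5h + 2.0 / 55.0 * k6h)
        c4 = ca + h_try * (25.0 / 216.0 * k1c + 1408.0 / 2565.0 * k3c + 2197.0 / 4104.0 * k4c - 0.2 * k5c)
        i4 = ip3 + h_try * (25.0 / 216.0 * k1i + 1408.0 / 2565.0 * k3i + 2197.0 / 4104.0 * k4i - 0.2 * k5i)
        h4 = h + h_try * (25.0 / 216.0 * k1h + 1408.0 / 2565.0 * k3h + 2197.0 / 4104.0 * k4h - 0.2 * k5h)
        err = abs(c5 - c4) / (tol * (1.0 + abs(c5)))
        e2 = abs(i5 - i4) / (tol * (1.0 + abs(i5)))
        if e2 > err:
            err = e2
        e3 = abs(h5 - h4) / (tol * (1.0 + abs(h5)))
        if e3 > err:
            err = e3
        if err <= 1.0:
            ca, ip3, h = c5, i5, h5
            t += h_try
            fac = 5.0 if err < 1e-10 else min(5.0, 0.9 * err ** -0.2)
            h_try = h_try * fac
        else:
            h_try = h_try * max(0.1, 0.9 * err ** -0.2)
            if h_try < dt * 1e-10:
                return ca, ip3, h, False
    return ca, ip3, h, True


@njit(cache=True, inline="always")
def astro_grid_step(ca, ip3, h, p, dt, weight_sum, noise_draw, tol):
    """Full grid step: IP3 spike increments, RKF45, noise, clamping."""
    ip3 = ip3 + p[A_DELTA_IP3] * weight_sum
    ca, ip3, h, ok = astro_integrate(ca, ip3, h, p, dt, tol)
    ca = ca + noise_draw
    if ca < 0.0:
        ca = 0.0
    elif ca > p[A_CA_TOT]:
        ca = p[A_CA_TOT]
    if h < 0.0:
        h = 0.0
    elif h > 1.0:
        h = 1.0
    if ip3 < 0.0:
        ip3 = 0.0
    return ca, ip3, h, ok


# ---------------------------------------------------------------------------
# AdEx neuron dynamics
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _adex_rhs(v, w, ge, dge, gi, dgi, p, i_ext):
    arg = (v - p[N_VT]) / p[N_DT]
    if arg > _MAX_EXP_ARG:
        arg = _MAX_EXP_ARG
    f = -p[N_GL] * (v - p[N_EL]) + p[N_GL] * p[N_DT] * math.exp(arg)
    i_syn = -ge * (v - p[N_EEXC]) - gi * (v - p[N_EINH])
    dv = (f - w + i_syn + i_ext) / p[N_CM]
    dw = (p[N_A] * (v - p[N_EL]) - w) / p[N_TAUW]
    d_ge = dge
    d_dge = -2.0 / p[N_TAUE] * dge - ge / (p[N_TAUE] * p[N_TAUE])
    d_gi = dgi
    d_dgi = -2.0 / p[N_TAUI] * dgi - gi / (p[N_TAUI] * p[N_TAUI])
    return dv, dw, d_ge, d_dge, d_gi, d_dgi


@njit(cache=True, inline="always")
def _alpha_decay(g, dg, tau, hs):
    """Exact propagation of the alpha-conductance pair over hs."""
    decay = math.exp(-hs / tau)
    slope = dg + g / tau
    g_new = decay * (g + hs * slope)
    dg_new = decay * (dg - hs * slope / tau)
    return g_new, dg_new


@njit(cache=True, inline="always")
def _vw_rhs(v, w, ge, gi, p, i_ext):
    """Membrane/adaptation derivatives given instantaneous conductances."""
    arg = (v - p[N_VT]) / p[N_DT]
    if arg > _MAX_EXP_ARG:
        arg = _MAX_EXP_ARG
    f = -p[N_GL] * (v - p[N_EL]) + p[N_GL] * p[N_DT] * math.exp(arg)
    i_syn = -ge * (v - p[N_EEXC]) - gi * (v - p[N_EINH])
    dv = (f - w + i_syn + i_ext) / p[N_CM]
    dw = (p[N_A] * (v - p[N_EL]) - w) / p[N_TAUW]
    return dv, dw


@njit(cache=True)
def neuron_grid_step(state, p, dt, i_sic, i_noise, tol):
    """One grid step of an AdEx neuron with RKF45 substepping.

    The alpha-conductance pairs form a linear subsystem and are
    propagated by their closed-form solution; the embedded RKF45 pair
    integrates only (v, w), sampling the exact conductances at the stage
    times.  ``state`` is the length-7 view (v, w, ge, dge, gi, dgi,
    refr) and is updated in place.  Returns (spiked, ok).  I_SIC and
    I_noise are held constant within the step.
    """
    v, w = state[0], state[1]
    ge, dge, gi, dgi = state[2], state[3], state[4], state[5]
    refr = state[6]
    # flush decayed conductances to exact zero; subnormal leftovers of the
    # exponential decay otherwise dominate the step cost
    if -1e-12 < ge < 1e-12 and -1e-12 < dge < 1e-12:
        ge = 0.0
        dge = 0.0
    if -1e-12 < gi < 1e-12 and -1e-12 < dgi < 1e-12:
        gi = 0.0
        dgi = 0.0
    i_ext = i_sic + i_noise
    spiked = False
    t = 0.0
    h_try = dt
    tau_e = p[N_TAUE]
    tau_i = p[N_TAUI]
    while t < dt - 1e-12:
        if refr > 0.0:
            hs = refr if refr < dt - t else dt - t
            ge, dge = _alpha_decay(ge, dge, tau_e, hs)
            gi, dgi = _alpha_decay(gi, dgi, tau_i, hs)
            w_inf = p[N_A] * (p[N_VRESET] - p[N_EL])
            w = w_inf + (w - w_inf) * math.exp(-hs / p[N_TAUW])
            v = p[N_VRESET]
            refr -= hs
            if refr < 1e-12:
                refr = 0.0
            t += hs
            h_try = dt - t
            continue
        if h_try > dt - t:
            h_try = dt - t
        h = h_try
        # exact conductances at the Fehlberg stage offsets
        ge2, _ = _alpha_decay(ge, dge, tau_e, 0.25 * h)
        gi2, _ = _alpha_decay(gi, dgi, tau_i, 0.25 * h)
        ge3, _ = _alpha_decay(ge, dge, tau_e, 0.375 * h)
        gi3, _ = _alpha_decay(gi, dgi, tau_i, 0.375 * h)
        ge4, _ = _alpha_decay(ge, dge, tau_e, 12.0 / 13.0 * h)
        gi4, _ = _alpha_decay(gi, dgi, tau_i, 12.0 / 13.0 * h)
        ge5, dge5 = _alpha_decay(ge, dge, tau_e, h)
        gi5, dgi5 = _alpha_decay(gi, dgi, tau_i, h)
        ge6, _ = _alpha_decay(ge, dge, tau_e, 0.5 * h)
        gi6, _ = _alpha_decay(gi, dgi, tau_i, 0.5 * h)
        k1v, k1w = _vw_rhs(v, w, ge, gi, p, i_ext)
        k2v, k2w = _vw_rhs(v + h * 0.25 * k1v, w + h * 0.25 * k1w,
                           ge2, gi2, p, i_ext)
        k3v, k3w = _vw_rhs(v + h * (3.0 / 32.0 * k1v + 9.0 / 32.0 * k2v),
                           w + h * (3.0 / 32.0 * k1w + 9.0 / 32.0 * k2w),
                           ge3, gi3, p, i_ext)
        k4v, k4w = _vw_rhs(
            v + h * (1932.0 / 2197.0 * k1v - 7200.0 / 2197.0 * k2v + 7296.0 / 2197.0 * k3v),
            w + h * (1932.0 / 2197.0 * k1w - 7200.0 / 2197.0 * k2w + 7296.0 / 2197.0 * k3w),
            ge4, gi4, p, i_ext)
        k5v, k5w = _vw_rhs(
            v + h * (439.0 / 216.0 * k1v - 8.0 * k2v + 3680.0 / 513.0 * k3v - 845.0 / 4104.0 * k4v),
            w + h * (439.0 / 216.0 * k1w - 8.0 * k2w + 3680.0 / 513.0 * k3w - 845.0 / 4104.0 * k4w),
            ge5, gi5, p, i_ext)
        k6v, k6w = _vw_rhs(
            v + h * (-8.0 / 27.0 * k1v + 2.0 * k2v - 3544.0 / 2565.0 * k3v + 1859.0 / 4104.0 * k4v - 11.0 / 40.0 * k5v),
            w + h * (-8.0 / 27.0 * k1w + 2.0 * k2w - 3544.0 / 2565.0 * k3w + 1859.0 / 4104.0 * k4w - 11.0 / 40.0 * k5w),
            ge6, gi6, p, i_ext)
        v5 = v + h * (16.0 / 135.0 * k1v + 6656.0 / 12825.0 * k3v + 28561.0 / 56430.0 * k4v - 9.0 / 50.0 * k5v + 2.0 / 55.0 * k6v)
        w5 = w + h * (16.0 / 135.0 * k1w + 6656.0 / 12825.0 * k3w + 28561.0 / 56430.0 * k4w - 9.0 / 50.0 * k5w + 2.0 / 55.0 * k6w)
        v4 = v + h * (25.0 / 216.0 * k1v + 1408.0 / 2565.0 * k3v + 2197.0 / 4104.0 * k4v - 0.2 * k5v)
        w4 = w + h * (25.0 / 216.0 * k1w + 1408.0 / 2565.0 * k3w + 2197.0 / 4104.0 * k4w - 0.2 * k5w)
        err = abs(v5 - v4) / (tol * (1.0 + abs(v5)))
        e2 = abs(w5 - w4) / (tol * (1.0 + abs(w5)))
        if e2 > err:
            err = e2
        if err <= 1.0:
            v, w = v5, w5
            ge, dge = ge5, dge5
            gi, dgi = gi5, dgi5
            t += h
            if v >= p[N_VPEAK]:
                spiked = True
                v = p[N_VRESET]
                w = w + p[N_B]
                refr = p[N_TREF]
            fac = 5.0 if err < 1e-10 else min(5.0, 0.9 * err ** -0.2)
            h_try = h * fac
        else:
            h_try = h * max(0.1, 0.9 * err ** -0.2)
            if h_try < dt * 1e-10:
                state[0], state[1], state[2], state[3] = v, w, ge, dge
                state[4], state[5], state[6] = gi, dgi, refr
                return spiked, False
    state[0], state[1], state[2], state[3] = v, w, ge, dge
    state[4], state[5], state[6] = gi, dgi, refr
    return spiked, True


@njit(cache=True)
def _neuron_grid_step_full_rk(state, p, dt, i_sic, i_noise, tol):
    """Reference variant: all six state variables under one RKF45 pair.

    Kept as an internal cross-check for the split integrator above.
    """
    v, w, ge, dge, gi, dgi, refr = (state[0], state[1], state[2], state[3],
                                    state[4], state[5], state[6])
    spiked = False
    t = 0.0
    h_try = dt
    while t < dt - 1e-12:
        if refr > 0.0:
            hs = refr if refr < dt - t else dt - t
            ge, dge = _alpha_decay(ge, dge, p[N_TAUE], hs)
            gi, dgi = _alpha_decay(gi, dgi, p[N_TAUI], hs)
            w_inf = p[N_A] * (p[N_VRESET] - p[N_EL])
            w = w_inf + (w - w_inf) * math.exp(-hs / p[N_TAUW])
            v = p[N_VRESET]
            refr -= hs
            if refr < 1e-12:
                refr = 0.0
            t += hs
            h_try = dt - t
            continue
        if h_try > dt - t:
            h_try = dt - t
        k1 = _adex_rhs(v, w, ge, dge, gi, dgi, p, i_sic + i_noise)
        k2 = _adex_rhs(v + h_try * 0.25 * k1[0], w + h_try * 0.25 * k1[1],
                       ge + h_try * 0.25 * k1[2], dge + h_try * 0.25 * k1[3],
                       gi + h_try * 0.25 * k1[4], dgi + h_try * 0.25 * k1[5],
                       p, i_sic + i_noise)
        k3 = _adex_rhs(v + h_try * (3.0 / 32.0 * k1[0] + 9.0 / 32.0 * k2[0]),
                       w + h_try * (3.0 / 32.0 * k1[1] + 9.0 / 32.0 * k2[1]),
                       ge + h_try * (3.0 / 32.0 * k1[2] + 9.0 / 32.0 * k2[2]),
                       dge + h_try * (3.0 / 32.0 * k1[3] + 9.0 / 32.0 * k2[3]),
                       gi + h_try * (3.0 / 32.0 * k1[4] + 9.0 / 32.0 * k2[4]),
                       dgi + h_try * (3.0 / 32.0 * k1[5] + 9.0 / 32.0 * k2[5]),
                       p, i_sic + i_noise)
        k4 = _adex_rhs(
            v + h_try * (1932.0 / 2197.0 * k1[0] - 7200.0 / 2197.0 * k2[0] + 7296.0 / 2197.0 * k3[0]),
            w + h_try * (1932.0 / 2197.0 * k1[1] - 7200.0 / 2197.0 * k2[1] + 7296.0 / 2197.0 * k3[1]),
            ge + h_try * (1932.0 / 2197.0 * k1[2] - 7200.0 / 2197.0 * k2[2] + 7296.0 / 2197.0 * k3[2]),
            dge + h_try * (1932.0 / 2197.0 * k1[3] - 7200.0 / 2197.0 * k2[3] + 7296.0 / 2197.0 * k3[3]),
            gi + h_try * (1932.0 / 2197.0 * k1[4] - 7200.0 / 2197.0 * k2[4] + 7296.0 / 2197.0 * k3[4]),
            dgi + h_try * (1932.0 / 2197.0 * k1[5] - 7200.0 / 2197.0 * k2[5] + 7296.0 / 2197.0 * k3[5]),
            p, i_sic + i_noise)
        k5 = _adex_rhs(
            v + h_try * (439.0 / 216.0 * k1[0] - 8.0 * k2[0] + 3680.0 / 513.0 * k3[0] - 845.0 / 4104.0 * k4[0]),
            w + h_try * (439.0 / 216.0 * k1[1] - 8.0 * k2[1] + 3680.0 / 513.0 * k3[1] - 845.0 / 4104.0 * k4[1]),
            ge + h_try * (439.0 / 216.0 * k1[2] - 8.0 * k2[2] + 3680.0 / 513.0 * k3[2] - 845.0 / 4104.0 * k4[2]),
            dge + h_try * (439.0 / 216.0 * k1[3] - 8.0 * k2[3] + 3680.0 / 513.0 * k3[3] - 845.0 / 4104.0 * k4[3]),
            gi + h_try * (439.0 / 216.0 * k1[4] - 8.0 * k2[4] + 3680.0 / 513.0 * k3[4] - 845.0 / 4104.0 * k4[4]),
            dgi + h_try * (439.0 / 216.0 * k1[5] - 8.0 * k2[5] + 3680.0 / 513.0 * k3[5] - 845.0 / 4104.0 * k4[5]),
            p, i_sic + i_noise)
        k6 = _adex_rhs(
            v + h_try * (-8.0 / 27.0 * k1[0] + 2.0 * k2[0] - 3544.0 / 2565.0 * k3[0] + 1859.0 / 4104.0 * k4[0] - 11.0 / 40.0 * k5[0]),
            w + h_try * (-8.0 / 27.0 * k1[1] + 2.0 * k2[1] - 3544.0 / 2565.0 * k3[1] + 1859.0 / 4104.0 * k4[1] - 11.0 / 40.0 * k5[1]),
            ge + h_try * (-8.0 / 27.0 * k1[2] + 2.0 * k2[2] - 3544.0 / 2565.0 * k3[2] + 1859.0 / 4104.0 * k4[2] - 11.0 / 40.0 * k5[2]),
            dge + h_try * (-8.0 / 27.0 * k1[3] + 2.0 * k2[3] - 3544.0 / 2565.0 * k3[3] + 1859.0 / 4104.0 * k4[3] - 11.0 / 40.0 * k5[3]),
            gi + h_try * (-8.0 / 27.0 * k1[4] + 2.0 * k2[4] - 3544.0 / 2565.0 * k3[4] + 1859.0 / 4104.0 * k4[4] - 11.0 / 40.0 * k5[4]),
            dgi + h_try * (-8.0 / 27.0 * k1[5] + 2.0 * k2[5] - 3544.0 / 2565.0 * k3[5] + 1859.0 / 4104.0 * k4[5] - 11.0 / 40.0 * k5[5]),
            p, i_sic + i_noise)
        err = 0.0
        y5 = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        v5 = v + h_try * (16.0 / 135.0 * k1[0] + 6656.0 / 12825.0 * k3[0] + 28561.0 / 56430.0 * k4[0] - 9.0 / 50.0 * k5[0] + 2.0 / 55.0 * k6[0])
        w5 = w + h_try * (16.0 / 135.0 * k1[1] + 6656.0 / 12825.0 * k3[1] + 28561.0 / 56430.0 * k4[1] - 9.0 / 50.0 * k5[1] + 2.0 / 55.0 * k6[1])
        ge5 = ge + h_try * (16.0 / 135.0 * k1[2] + 6656.0 / 12825.0 * k3[2] + 28561.0 / 56430.0 * k4[2] - 9.0 / 50.0 * k5[2] + 2.0 / 55.0 * k6[2])
        dge5 = dge + h_try * (16.0 / 135.0 * k1[3] + 6656.0 / 12825.0 * k3[3] + 28561.0 / 56430.0 * k4[3] - 9.0 / 50.0 * k5[3] + 2.0 / 55.0 * k6[3])
        gi5 = gi + h_try * (16.0 / 135.0 * k1[4] + 6656.0 / 12825.0 * k3[4] + 28561.0 / 56430.0 * k4[4] - 9.0 / 50.0 * k5[4] + 2.0 / 55.0 * k6[4])
        dgi5 = dgi + h_try * (16.0 / 135.0 * k1[5] + 6656.0 / 12825.0 * k3[5] + 28561.0 / 56430.0 * k4[5] - 9.0 / 50.0 * k5[5] + 2.0 / 55.0 * k6[5])
        v4 = v + h_try * (25.0 / 216.0 * k1[0] + 1408.0 / 2565.0 * k3[0] + 2197.0 / 4104.0 * k4[0] - 0.2 * k5[0])
        w4 = w + h_try * (25.0 / 216.0 * k1[1] + 1408.0 / 2565.0 * k3[1] + 2197.0 / 4104.0 * k4[1] - 0.2 * k5[1])
        ge4 = ge + h_try * (25.0 / 216.0 * k1[2] + 1408.0 / 2565.0 * k3[2] + 2197.0 / 4104.0 * k4[2] - 0.2 * k5[2])
        dge4 = dge + h_try * (25.0 / 216.0 * k1[3] + 1408.0 / 2565.0 * k3[3] + 2197.0 / 4104.0 * k4[3] - 0.2 * k5[3])
        gi4 = gi + h_try * (25.0 / 216.0 * k1[4] + 1408.0 / 2565.0 * k3[4] + 2197.0 / 4104.0 * k4[4] - 0.2 * k5[4])
        dgi4 = dgi + h_try * (25.0 / 216.0 * k1[5] + 1408.0 / 2565.0 * k3[5] + 2197.0 / 4104.0 * k4[5] - 0.2 * k5[5])
        for pair in ((v5, v4), (w5, w4), (ge5, ge4), (dge5, dge4),
                     (gi5, gi4), (dgi5, dgi4)):
            e = abs(pair[0] - pair[1]) / (tol * (1.0 + abs(pair[0])))
            if e > err:
                err = e
        if err <= 1.0:
            v, w, ge, dge, gi, dgi = v5, w5, ge5, dge5, gi5, dgi5
            t += h_try
            if v >= p[N_VPEAK]:
                spiked = True
                v = p[N_VRESET]
                w = w + p[N_B]
                refr = p[N_TREF]
            fac = 5.0 if err < 1e-10 else min(5.0, 0.9 * err ** -0.2)
            h_try = h_try * fac
        else:
            h_try = h_try * max(0.1, 0.9 * err ** -0.2)
            if h_try < dt * 1e-10:
                state[0], state[1], state[2], state[3] = v, w, ge, dge
                state[4], state[5], state[6] = gi, dgi, refr
                return spiked, False
    state[0], state[1], state[2], state[3] = v, w, ge, dge
    state[4], state[5], state[6] = gi, dgi, refr
    return spiked, True


# ---------------------------------------------------------------------------
# Network propagation loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_kernel(
    n_steps, dt, tol, master_seed,
    np_arr, ns_arr,                       # neuron params (N,15), states (N,7)
    ap_arr, as_arr, is_surr,              # astro params (M,18), states (M,3), flags
    lam_step_n, w_drive_n, noise_sd_n,    # per-neuron drives
    lam_step_a, w_drive_a,                # per-astrocyte drives
    indptr, e_tgt, e_w, e_d, e_code,      # spike CSR by source neuron
    so_astro, so_tgt, so_w, so_d,         # SIC (third_out) edges
    buf_exc, buf_inh, buf_ip3, f_hist,    # ring buffers
    rec_interval, rec_n_ids, rec_a_ids, sic_ids,
    rec_v, rec_w, rec_ca, rec_ip3, rec_isic,
    spike_cell, spike_step,
):
    """Advance the network ``n_steps`` grid steps.

    Returns (n_spikes, overflow, integration_error_cell).  The error cell
    is -1 when integration succeeded everywhere; otherwise it is the
    global id of the first cell whose adaptive integrator underflowed.
    """
    n_neurons = ns_arr.shape[0]
    n_astro = as_arr.shape[0]
    buf_len = buf_exc.shape[0]
    f_len = f_hist.shape[0]
    cap = spike_cell.shape[0]
    n_spikes = 0
    overflow = False
    err_cell = -1
    isic = np.zeros(n_neurons, dtype=np.float64)
    sqrt_dt = math.sqrt(dt)

    for k in range(n_steps):
        slot = k % buf_len
        # (2) continuous SIC delivery with per-edge delay
        for i in range(n_neurons):
            isic[i] = 0.0
        for e in range(so_astro.shape[0]):
            past = (k - so_d[e]) % f_len
            isic[so_tgt[e]] += so_w[e] * f_hist[past, so_astro[e]]
        # (1,3,4) deliver spikes, draw drives, step neurons
        for i in range(n_neurons):
            w_exc = buf_exc[slot, i]
            w_inh = buf_inh[slot, i]
            buf_exc[slot, i] = 0.0
            buf_inh[slot, i] = 0.0
            if lam_step_n[i] > 0.0:
                cnt = _rand_poisson(lam_step_n[i], master_seed, i, 1, k)
                w_exc += cnt * w_drive_n[i]
            p = np_arr[i]
            if w_exc != 0.0:
                ns_arr[i, 3] += w_exc * _E / p[N_TAUE]
            if w_inh != 0.0:
                ns_arr[i, 5] += w_inh * _E / p[N_TAUI]
            i_noise = 0.0
            if noise_sd_n[i] > 0.0:
                i_noise = noise_sd_n[i] * _rand_normal(master_seed, i, 0, k)
            spiked, ok = neuron_grid_step(ns_arr[i], p, dt, isic[i], i_noise, tol)
            if not ok and err_cell < 0:
                err_cell = i
            if spiked:
                if n_spikes < cap:
                    spike_cell[n_spikes] = i
                    spike_step[n_spikes] = k
                else:
                    overflow = True
                n_spikes += 1
                for ei in range(indptr[i], indptr[i + 1]):
                    dest = (k + e_d[ei]) % buf_len
                    code = e_code[ei]
                    if code == 0:
                        buf_exc[dest, e_tgt[ei]] += e_w[ei]
                    elif code == 1:
                        buf_inh[dest, e_tgt[ei]] += e_w[ei]
                    else:
                        buf_ip3[dest, e_tgt[ei]] += e_w[ei]
        # (4b) step astrocytes, update SIC history
        fslot = k % f_len
        for j in range(n_astro):
            w_sum = buf_ip3[slot, j]
            buf_ip3[slot, j] = 0.0
            if lam_step_a[j] > 0.0:
                cnt = _rand_poisson(lam_step_a[j], master_seed, j, 3, k)
                w_sum += cnt * w_drive_a[j]
            pa = ap_arr[j]
            if is_surr[j] == 1:
                f_hist[fslot, j] = pa[A_SIC_CONST]
                continue
            noise = 0.0
            if pa[A_NOISE_SD] > 0.0:
                noise = pa[A_NOISE_SD] * sqrt_dt * _rand_normal(master_seed, j, 2, k)
            ca, ip3, hh, ok = astro_grid_step(
                as_arr[j, 0], as_arr[j, 1], as_arr[j, 2], pa, dt, w_sum, noise, tol)
            as_arr[j, 0] = ca
            as_arr[j, 1] = ip3
            as_arr[j, 2] = hh
            if not ok and err_cell < 0:
                err_cell = n_neurons + j
            f_hist[fslot, j] = sic_from_ca(ca, pa[A_SIC_TH], pa[A_SIC_SCALE])
        # (5) sampled recording of continuous traces
        if rec_interval > 0 and (k + 1) % rec_interval == 0:
            row = (k + 1) // rec_interval - 1
            if row < rec_v.shape[0]:
                for idx in range(rec_n_ids.shape[0]):
                    rec_v[row, idx] = ns_arr[rec_n_ids[idx], 0]
                    rec_w[row, idx] = ns_arr[rec_n_ids[idx], 1]
                for idx in range(rec_a_ids.shape[0]):
                    rec_ca[row, idx] = as_arr[rec_a_ids[idx], 0]
                    rec_ip3[row, idx] = as_arr[rec_a_ids[idx], 1]
                for idx in range(sic_ids.shape[0]):
                    rec_isic[row, idx] = isic[sic_ids[idx]]
    return n_spikes, overflow, err_cell
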
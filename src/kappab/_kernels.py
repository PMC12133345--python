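"""Numba-compiled inner loops: fixed-step DDE integration and Gillespie SSA.

All kernels are deterministic functions of their arguments (SSA kernels
seed numpy's legacy RNG internally), so identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fr(I, Km2, nH2):
    x = (max(I, 0.0) / Km2) ** nH2
    return 1.0 / (1.0 + x)


@njit(cache=True)
def rk4_dde(b, k2, kP, kd, Km2, nH2, n_steps, h, lag, g0, i0, rec_every):
    """RK4 on the delayed system with constant history (g0, i0) on [-T, 0].

    ``lag`` is the delay in steps (T rounded to a multiple of h).  For
    lag > 0 the delayed gene value is the stored grid value at t - T and is
    reused by all four stages; for lag == 0 the system is an ODE and the
    stages use their own updated state (standard RK4).  The gene history is
    kept in a ring buffer of ``lag`` steps and the output is recorded every
    ``rec_every`` steps, so memory stays flat for long horizons.
    """
    n_rec = n_steps // rec_every + 1
    G = np.empty(n_rec)
    I = np.empty(n_rec)
    hist = np.empty(max(lag, 1))
    g = g0
    i = i0
    G[0] = g
    I[0] = i
    for n in range(n_steps):
        if lag == 0:
            k1g = b * (1.0 - g) - k2 * _fr(i, Km2, nH2) * g
            k1i = kP * g - kd * i
            g2 = g + 0.5 * h * k1g
            i2 = i + 0.5 * h * k1i
            k2g = b * (1.0 - g2) - k2 * _fr(i2, Km2, nH2) * g2
            k2i = kP * g2 - kd * i2
            g3 = g + 0.5 * h * k2g
            i3 = i + 0.5 * h * k2i
            k3g = b * (1.0 - g3) - k2 * _fr(i3, Km2, nH2) * g3
            k3i = kP * g3 - kd * i3
            g4 = g + h * k3g
            i4 = i + h * k3i
            k4g = b * (1.0 - g4) - k2 * _fr(i4, Km2, nH2) * g4
            k4i = kP * g4 - kd * i4
        else:
            slot = n % lag
            gd = g0 if n < lag else hist[slot]
            hist[slot] = g  # G_n, read back at step n + lag
            act = b * (1.0 - gd)
            k1g = act - k2 * _fr(i, Km2, nH2) * g
            k1i = kP * g - kd * i
            g2 = g + 0.5 * h * k1g
            i2 = i + 0.5 * h * k1i
            k2g = act - k2 * _fr(i2, Km2, nH2) * g2
            k2i = kP * g2 - kd * i2
            g3 = g + 0.5 * h * k2g
            i3 = i + 0.5 * h * k2i
            k3g = act - k2 * _fr(i3, Km2, nH2) * g3
            k3i = kP * g3 - kd * i3
            g4 = g + h * k3g
            i4 = i + h * k3i
            k4g = act - k2 * _fr(i4, Km2, nH2) * g4
            k4i = kP * g4 - kd * i4
        g = g + (h / 6.0) * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        i = i + (h / 6.0) * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        if (n + 1) % rec_every == 0:
            G[(n + 1) // rec_every] = g
            I[(n + 1) // rec_every] = i
    return G, I


@njit(cache=True)
def ssa_reduced_kernel(k1fa, k2, kP, kd, Km2, nH2, i0, t_end, max_events, seed):
    """Two-channel birth-death SSA on I with rates S+(I), kd I."""
    np.random.seed(seed)
    times = np.empty(max_events + 1)
    states = np.empty(max_events + 1, dtype=np.int64)
    t = 0.0
    I = i0
    times[0] = 0.0
    states[0] = I
    n = 0
    while n < max_events:
        sp = k1fa * kP / (k1fa + k2 * _fr(float(I), Km2, nH2)) if k1fa > 0.0 else 0.0
        sm = kd * I
        a0 = sp + sm
        if a0 <= 0.0:
            break
        t += -np.log(np.random.random()) / a0
        if t > t_end:
            break
        if np.random.random() * a0 < sp:
            I += 1
        else:
            I -= 1
        n += 1
        times[n] = t
        states[n] = I
    return times[: n + 1], states[: n + 1]


@njit(cache=True)
def ssa_full_kernel(k1fa, k2, kP, kd, Km2, nH2, g0, i0, t_end, max_events, seed):
    """Four-channel SSA on a single gene copy: (de)activation, production, decay."""
    np.random.seed(seed)
    times = np.empty(max_events + 1)
    states = np.empty(max_events + 1, dtype=np.int64)
    genes = np.empty(max_events + 1, dtype=np.int64)
    t = 0.0
    g = g0
    I = i0
    times[0] = 0.0
    states[0] = I
    genes[0] = g
    n = 0
    while n < max_events:
        a_act = k1fa * (1 - g)
        a_deact = k2 * _fr(float(I), Km2, nH2) * g
        a_prod = kP * g
        a_deg = kd * I
        a0 = a_act + a_deact + a_prod + a_deg
        if a0 <= 0.0:
            break
        t += -np.log(np.random.random()) / a0
        if t > t_end:
            break
        r = np.random.random() * a0
        if r < a_act:
            g = 1
        elif r < a_act + a_deact:
            g = 0
        elif r < a_act + a_deact + a_prod:
            I += 1
        else:
            I -= 1
        n += 1
        times[n] = t
        states[n] = I
        genes[n] = g
    return times[: n + 1], states[: n + 1], genes[: n + 1]


@njit(cache=True)
def ssa_colored_kernel(
    k1fa, k2, kP, kd, Km2, nH2, i0, t_end, max_events, seed, D, tau, dt_ou, eps0
):
    """Next-reaction SSA with OU-modulated degradation rate kd (1 + ε(t)).

    Each channel carries a unit-exponential internal clock; hazards are
    integrated piecewise-constant over OU grid cells of width dt_ou (ε is
    frozen within a cell).  Negative modulated rates are clamped at zero;
    the clamp count is returned for diagnostics.
    """
    np.random.seed(seed)
    times = np.empty(max_events + 1)
    states = np.empty(max_events + 1, dtype=np.int64)
    eps_tr = np.empty(max_events + 1)
    decay = np.exp(-dt_ou / tau)
    sdev = np.sqrt(D / tau * (1.0 - decay * decay))
    t = 0.0
    I = i0
    eps = eps0
    cell_end = dt_ou
    P1 = -np.log(np.random.random())
    P2 = -np.log(np.random.random())
    T1 = 0.0
    T2 = 0.0
    times[0] = 0.0
    states[0] = I
    eps_tr[0] = eps
    n = 0
    n_clamp = 0
    while n < max_events and t < t_end:
        r1 = k1fa * kP / (k1fa + k2 * _fr(float(I), Km2, nH2)) if k1fa > 0.0 else 0.0
        kd_eff = kd * (1.0 + eps)
        if kd_eff < 0.0:
            kd_eff = 0.0
            n_clamp += 1
        r2 = kd_eff * I
        dt1 = (P1 - T1) / r1 if r1 > 0.0 else np.inf
        dt2 = (P2 - T2) / r2 if r2 > 0.0 else np.inf
        if dt1 <= dt2:
            dtm = dt1
            which = 1
        else:
            dtm = dt2
            which = 2
        if t + dtm < cell_end:
            t += dtm
            if t > t_end:
                break
            T1 += r1 * dtm
            T2 += r2 * dtm
            if which == 1:
                I += 1
                P1 += -np.log(np.random.random())
            else:
                I -= 1
                P2 += -np.log(np.random.random())
            n += 1
            times[n] = t
            states[n] = I
            eps_tr[n] = eps
        else:
            dtc = cell_end - t
            T1 += r1 * dtc
            T2 += r2 * dtc
            t = cell_end
            cell_end += dt_ou
            eps = eps * decay + sdev * np.random.standard_normal()
    return times[: n + 1], states[: n + 1], eps_tr[: n + 1], n_clamp
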
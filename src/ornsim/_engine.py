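"""Numba-accelerated forward-Euler integration kernels.

The kernels are deliberately free of Python objects: parameters arrive as
scalars, state as contiguous float64 arrays.  If numba is unavailable the
same functions run as pure Python (orders of magnitude slower, but
numerically identical), so the package degrades gracefully.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def euler_kinetics(
    L_air: np.ndarray,
    dt: float,
    R_tot: float,
    N_tot: float,
    k_i: float,
    k1: float,
    k_m1: float,
    k2: float,
    k_m2: float,
    k3: float,
    k_m3: float,
    k4: float,
    n: float,
    L0: float,
    R0: float,
    Rstar0: float,
    N0: float,
):
    """Integrate the reduced 4-state transduction cascade with forward Euler.

    ``L_air`` is the airborne odorant concentration sampled on the dt grid;
    the returned trajectories share that grid.  States are clamped at zero
    after each step; the largest pre-clamp undershoot is returned so the
    caller can detect numerical instability at too-coarse dt.
    """
    m = L_air.shape[0]
    L = np.empty(m)
    R = np.empty(m)
    Rstar = np.empty(m)
    N = np.empty(m)
    L[0] = L0
    R[0] = R0
    Rstar[0] = Rstar0
    N[0] = N0
    undershoot = 0.0
    l, r, rs, nn = L0, R0, Rstar0, N0
    for i in range(1, m):
        lc = l if l > 0.0 else 0.0
        ln = lc**n if lc > 0.0 else 0.0
        a1 = k1 * ln + k_m1
        dl = (
            k_i * L_air[i - 1]
            - n * a1 * r
            - n * k_m1 * rs
            - (k3 * lc + k_m3) * nn
            + n * k_m1 * R_tot
            + k_m3 * N_tot
        )
        dr = -a1 * r - k_m1 * rs + k_m1 * R_tot
        drs = -k2 * r - (k2 + k_m2) * rs + k2 * R_tot
        dn = -(k3 * lc + k_m3 + k4) * nn + (k_m3 + k4) * N_tot
        l += dt * dl
        r += dt * dr
        rs += dt * drs
        nn += dt * dn
        if l < 0.0:
            if -l > undershoot:
                undershoot = -l
            l = 0.0
        if r < 0.0:
            if -r > undershoot:
                undershoot = -r
            r = 0.0
        if rs < 0.0:
            if -rs > undershoot:
                undershoot = -rs
            rs = 0.0
        if nn < 0.0:
            if -nn > undershoot:
                undershoot = -nn
            nn = 0.0
        L[i] = l
        R[i] = r
        Rstar[i] = rs
        N[i] = nn
    return L, R, Rstar, N, undershoot


@njit(cache=True)
def euler_neuron(
    Rstar: np.ndarray,
    dt: float,
    C_m: float,
    g_L: float,
    gamma: float,
    E_L: float,
    E_R: float,
    V_reset: float,
    theta0: float,
    delta: float,
    tau: float,
    t_ref: float,
    adaptive: bool,
    record: bool,
):
    """Integrate the membrane equation and emit spikes.

    Per-step order: membrane Euler update with the current step's R*,
    threshold decay (adaptive mode), crossing test V >= theta, then reset
    and threshold jump delta/tau (adaptive) or refractory clamp (constant
    mode).  Spike times are grid times of the crossing step.  Returns
    (V trace, theta trace, spike step indices, spike count); traces are
    empty arrays when ``record`` is False.
    """
    m = Rstar.shape[0]
    if record:
        V_out = np.empty(m)
        th_out = np.empty(m)
    else:
        V_out = np.empty(0)
        th_out = np.empty(0)
    spikes = np.empty(m, dtype=np.int64)
    nspk = 0
    v = E_L
    th = theta0
    refr_left = 0.0
    if record:
        V_out[0] = v
        th_out[0] = th
    for i in range(1, m):
        if refr_left > 0.0:
            # constant-threshold mode: voltage clamped, no crossing test
            refr_left -= dt
            v = V_reset
        else:
            rs = Rstar[i]
            dv = (-g_L * (v - E_L) - gamma * rs * (v - E_R)) / C_m
            v += dt * dv
        if adaptive:
            th += dt * (-(th - theta0) / tau)
        if refr_left <= 0.0 and v >= th:
            spikes[nspk] = i
            nspk += 1
            v = V_reset
            if adaptive:
                th += delta / tau
            else:
                refr_left = t_ref
        if record:
            V_out[i] = v
            th_out[i] = th
    return V_out, th_out, spikes, nspk
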
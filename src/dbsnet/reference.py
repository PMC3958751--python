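"""Reference integrators for verification.

These integrate the exact cell-model right-hand sides of
:mod:`dbsnet.neurons` (direct evaluation of every rate function, no
lookup tables) with classical RK4 at an arbitrary time step.  They are
deliberately simple, single-cell / single-cable implementations used as
independent oracles for the production kernel: runs at one-tenth of the
production step bound the integration error, and runs at the production
step isolate the table-interpolation error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import neurons

__all__ = ["integrate_soma", "integrate_stn", "integrate_gpe",
           "integrate_izh", "integrate_cable", "upward_crossings"]


@njit(cache=True)
def integrate_soma(y0, i_inj, dt, n_steps, pp):
    """RK4 trajectory of the cortical soma; returns Vm at every step.

    ``i_inj`` is the injected current per step (uA/cm^2, length
    n_steps, held constant over each step).
    """
    y = y0.copy()
    out = np.empty(n_steps + 1)
    out[0] = y[0]
    for s in range(n_steps):
        i = i_inj[s]
        k1 = neurons.soma_rhs(y, i, pp)
        k2 = neurons.soma_rhs(y + 0.5 * dt * k1, i, pp)
        k3 = neurons.soma_rhs(y + 0.5 * dt * k2, i, pp)
        k4 = neurons.soma_rhs(y + dt * k3, i, pp)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[s + 1] = y[0]
    return out


@njit(cache=True)
def integrate_stn(y0, i_syn, dt, n_steps, pp):
    """RK4 trajectory of the STN model; returns the full state history
    column 0 = Vm, column 12 = Ca."""
    y = y0.copy()
    out = np.empty((n_steps + 1, 13))
    out[0] = y
    for s in range(n_steps):
        i = i_syn[s]
        k1 = neurons.stn_rhs(y, i, pp)
        k2 = neurons.stn_rhs(y + 0.5 * dt * k1, i, pp)
        k3 = neurons.stn_rhs(y + 0.5 * dt * k2, i, pp)
        k4 = neurons.stn_rhs(y + dt * k3, i, pp)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[s + 1] = y
    return out


@njit(cache=True)
def integrate_gpe(y0, i_syn, dt, n_steps, pp):
    y = y0.copy()
    out = np.empty((n_steps + 1, 5))
    out[0] = y
    for s in range(n_steps):
        i = i_syn[s]
        k1 = neurons.gpe_rhs(y, i, pp)
        k2 = neurons.gpe_rhs(y + 0.5 * dt * k1, i, pp)
        k3 = neurons.gpe_rhs(y + 0.5 * dt * k2, i, pp)
        k4 = neurons.gpe_rhs(y + dt * k3, i, pp)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[s + 1] = y
    return out


@njit(cache=True)
def integrate_izh(v0, u0, i_inj, dt, n_steps, a, b, c, d, v_peak):
    """RK4 + after-step reset for the interneuron; returns (v trace,
    spike count)."""
    v = v0
    u = u0
    out = np.empty(n_steps + 1)
    out[0] = v
    spikes = 0
    for s in range(n_steps):
        i = i_inj[s]
        k1v, k1u = neurons.izh_rhs(v, u, i, a, b)
        k2v, k2u = neurons.izh_rhs(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u,
                                   i, a, b)
        k3v, k3u = neurons.izh_rhs(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u,
                                   i, a, b)
        k4v, k4u = neurons.izh_rhs(v + dt * k3v, u + dt * k3u, i, a, b)
        v = v + (dt / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        u = u + (dt / 6.0) * (k1u + 2 * k2u + 2 * k3u + k4u)
        if v >= v_peak:
            v = c
            u = u + d
            spikes += 1
        out[s + 1] = v
    return out, spikes


@njit(cache=True)
def _cable_rhs(V, G, i_inj, istim, kinds, areas, cm, gna, gk, gkd, gleak,
               eleak, edges, g_edge, fcoef, valve, junction_edge,
               pp_soma, kin, kin_coll, e_na, e_k):
    C = V.shape[0]
    dV = np.zeros(C)
    dG = np.zeros((C, 5))
    iax = np.zeros(C)
    for e in range(edges.shape[0]):
        a = edges[e, 0]
        b = edges[e, 1]
        cur = g_edge[e] * (V[b] - V[a]) + fcoef[e] * istim
        if not (valve and e == junction_edge):
            iax[a] += cur
        iax[b] -= cur
    for c in range(C):
        v = V[c]
        drive = iax[c] / areas[c] + i_inj[c]
        if kinds[c] == 0:   # soma
            am, bm, ah, bh, an, bn, p_inf, tau_p = neurons.soma_gate_rates(
                v, pp_soma[9], pp_soma[6])
            m, h, n, p = G[c, 0], G[c, 1], G[c, 2], G[c, 3]
            i_ion = (gna[c] * m ** 3 * h * (v - pp_soma[2])
                     + gk[c] * n ** 4 * (v - pp_soma[4])
                     + gkd[c] * p * (v - pp_soma[4])
                     + gleak[c] * (v - eleak[c]))
            dG[c, 0] = am * (1 - m) - bm * m
            dG[c, 1] = ah * (1 - h) - bh * h
            dG[c, 2] = an * (1 - n) - bn * n
            dG[c, 3] = (p_inf - p) / tau_p
        else:
            kk = kin_coll if kinds[c] == 4 else kin
            am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b = \
                neurons.axon_gate_rates(v, kk)
            m, h, n, ag, bg = G[c, 0], G[c, 1], G[c, 2], G[c, 3], G[c, 4]
            hh = h * h if kk[22] == 2.0 else h
            i_ion = (gna[c] * m ** 3 * hh * (v - e_na)
                     + gk[c] * n * (v - e_k)
                     + gkd[c] * ag * bg * (v - e_k)
                     + gleak[c] * (v - eleak[c]))
            dG[c, 0] = am * (1 - m) - bm * m
            dG[c, 1] = ah * (1 - h) - bh * h
            dG[c, 2] = an * (1 - n) - bn * n
            dG[c, 3] = (a_inf - ag) / tau_a
            dG[c, 4] = (b_inf - bg) / tau_b
        dV[c] = (-i_ion + drive) / cm[c]
    return dV, dG


@njit(cache=True)
def integrate_cable(V0, G0, i_inj, istim, dt, kinds, areas, cm, gna, gk,
                    gkd, gleak, eleak, edges, g_edge, fcoef, valve,
                    junction_edge, pp_soma, kin, kin_coll, e_na, e_k,
                    rec_dec):
    """RK4 trajectory of a single multicompartment cortical neuron.

    ``i_inj`` (n_steps x C, uA/cm^2) and ``istim`` (n_steps, mA) are
    held constant over each step.  Returns the decimated Vm history
    (rows x C).
    """
    n_steps = i_inj.shape[0]
    V = V0.copy()
    G = G0.copy()
    n_rec = (n_steps + rec_dec - 1) // rec_dec + 1
    out = np.empty((n_rec, V.shape[0]))
    row = 0
    for s in range(n_steps):
        if s % rec_dec == 0:
            out[row] = V
            row += 1
        k1V, k1G = _cable_rhs(V, G, i_inj[s], istim[s], kinds, areas, cm,
                              gna, gk, gkd, gleak, eleak, edges, g_edge,
                              fcoef, valve, junction_edge, pp_soma, kin,
                              kin_coll, e_na, e_k)
        k2V, k2G = _cable_rhs(V + 0.5 * dt * k1V, G + 0.5 * dt * k1G,
                              i_inj[s], istim[s], kinds, areas, cm, gna, gk,
                              gkd, gleak, eleak, edges, g_edge, fcoef,
                              valve, junction_edge, pp_soma, kin, kin_coll,
                              e_na, e_k)
        k3V, k3G = _cable_rhs(V + 0.5 * dt * k2V, G + 0.5 * dt * k2G,
                              i_inj[s], istim[s], kinds, areas, cm, gna, gk,
                              gkd, gleak, eleak, edges, g_edge, fcoef,
                              valve, junction_edge, pp_soma, kin, kin_coll,
                              e_na, e_k)
        k4V, k4G = _cable_rhs(V + dt * k3V, G + dt * k3G, i_inj[s],
                              istim[s], kinds, areas, cm, gna, gk, gkd,
                              gleak, eleak, edges, g_edge, fcoef, valve,
                              junction_edge, pp_soma, kin, kin_coll,
                              e_na, e_k)
        V = V + (dt / 6.0) * (k1V + 2 * k2V + 2 * k3V + k4V)
        G = G + (dt / 6.0) * (k1G + 2 * k2G + 2 * k3G + k4G)
    out[row] = V
    return out[:row + 1]


def upward_crossings(v: np.ndarray, threshold: float = -10.0,
                     dt: float = 0.01, lockout: float = 1.0) -> np.ndarray:
    """Spike times (ms) from a membrane trace by threshold crossing with
    a refractory lockout (numpy implementation used by tests)."""
    v = np.asarray(v)
    above = v >= threshold
    cross = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for idx in cross:
        t = idx * dt
        if t - last >= lockout:
            times.append(t)
            last = t
    return np.asarray(times)
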
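"""Single-cell dynamical models.

Five cell models are defined:

* **Cortical soma** -- minimal Hodgkin-Huxley regular-spiking pyramidal
  model with fast Na+ (``I_Na``), delayed-rectifier K+ (``I_Kd``), the
  slow non-inactivating K+ adaptation current (``I_M``) and leak.
* **Cortical axon compartment** -- HH membrane for the AIS, nodes of
  Ranvier, internodes and the unmyelinated collateral, with fast Na+
  (``I_Na+``), delayed-rectifier K+ (``I_K+``), a rapidly activating /
  slowly inactivating D-type K+ current (``I_Kd``) and leak.  Channel
  densities depend only on the compartment kind.
* **Interneuron** -- two-variable quadratic spiking model with an
  explicit after-spike reset (fast-spiking parameterization).
* **STN neuron** -- single-compartment model with Na, K, A-type K,
  L-type Ca, T-type Ca, Ca-activated K and leak currents and an
  intracellular calcium pool; reproduces rebound/plateau behavior.
* **GPe neuron** -- single-compartment pallidal model with leak, Na, K,
  T-type Ca, high-threshold Ca and afterhyperpolarization currents.

Each model exposes a pure right-hand-side function operating on a flat
state vector (numba-compiled, shared by the reference integrators and
used to generate the lookup tables of the production kernel) and a typed
dataclass API mirroring the state fields.

Sign conventions: every ionic current is written as an outward-positive
term ``g x (V - E_rev)`` and enters the membrane equation with a minus
sign, so depolarizing (inward / excitatory) input increases ``dVm/dt``.
Synaptic currents follow the same convention (see :mod:`dbsnet.network`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from numba import njit

__all__ = [
    "CorticalSomaState", "AxonCompartmentState", "InterneuronState",
    "STNState", "GPeState", "ChannelDensityTable", "AXON_KINDS",
    "soma_derivatives", "axon_derivatives", "interneuron_step",
    "stn_derivatives", "gpe_derivatives",
    "soma_rhs", "axon_rhs", "stn_rhs", "gpe_rhs", "izh_rhs",
    "pack_soma_params", "pack_axon_kinetics", "pack_stn_params",
    "pack_gpe_params", "soma_init", "axon_init", "stn_init", "gpe_init",
]

AXON_KINDS = ("ais", "node", "internode", "collateral")

# State vector layouts (index 0 is always Vm, mV)
SOMA_NSTATE = 5      # v, m, h, n, p
AXON_NSTATE = 6      # v, m, h, n, a, b
STN_NSTATE = 13      # v, m, h, n, a, b, c, d1, d2, p, q, r, ca
GPE_NSTATE = 5       # v, h, n, r, ca


@njit(cache=True)
def _efun(x):
    """x / (exp(x) - 1), continuous through x = 0."""
    if abs(x) < 1e-9:
        return 1.0 - x / 2.0
    return x / (math.exp(x) - 1.0)


# ----------------------------------------------------------------------
# Cortical soma (regular-spiking pyramidal cell)
#
# Parameter array layout:
# [cm, g_na, e_na, g_kd, e_k, g_m, tau_max, g_leak, e_leak, v_t]

def pack_soma_params(p: dict) -> np.ndarray:
    s = p["soma"]
    return np.array([s["cm"], s["g_na"], s["e_na"], s["g_kd"], s["e_k"],
                     s["g_m"], s["tau_max_m"], s["g_leak"], s["e_leak"],
                     s["v_t"]], dtype=np.float64)


@njit(cache=True)
def soma_gate_rates(v, v_t, tau_max):
    """Return (am, bm, ah, bh, an, bn, p_inf, tau_p) at potential v."""
    am = 1.28 * _efun(-(v - v_t - 13.0) / 4.0)
    bm = 1.4 * _efun((v - v_t - 40.0) / 5.0)
    ah = 0.128 * math.exp(-(v - v_t - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(v - v_t - 40.0) / 5.0))
    an = 0.16 * _efun(-(v - v_t - 15.0) / 5.0)
    bn = 0.5 * math.exp(-(v - v_t - 10.0) / 40.0)
    p_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * math.exp((v + 35.0) / 20.0)
                       + math.exp(-(v + 35.0) / 20.0))
    return am, bm, ah, bh, an, bn, p_inf, tau_p


@njit(cache=True)
def soma_rhs(y, i_ext, pp):
    """dy/dt of the soma state [v, m, h, n, p]; i_ext in uA/cm^2."""
    v, m, h, n, p = y[0], y[1], y[2], y[3], y[4]
    cm, g_na, e_na, g_kd, e_k = pp[0], pp[1], pp[2], pp[3], pp[4]
    g_m, tau_max, g_leak, e_leak, v_t = pp[5], pp[6], pp[7], pp[8], pp[9]
    am, bm, ah, bh, an, bn, p_inf, tau_p = soma_gate_rates(v, v_t, tau_max)
    i_na = g_na * m * m * m * h * (v - e_na)
    i_kd = g_kd * n * n * n * n * (v - e_k)
    i_m = g_m * p * (v - e_k)
    i_leak = g_leak * (v - e_leak)
    dy = np.empty(5)
    dy[0] = (-i_na - i_kd - i_m - i_leak + i_ext) / cm
    dy[1] = am * (1.0 - m) - bm * m
    dy[2] = ah * (1.0 - h) - bh * h
    dy[3] = an * (1.0 - n) - bn * n
    dy[4] = (p_inf - p) / tau_p
    return dy


# ----------------------------------------------------------------------
# Cortical axon compartment
#
# Kinetics array layout:
# 0 e_na, 1 e_k, 2 e_leak, 3 unused, 4..6 kd a theta/sigma/tau,
# 7..9 kd b theta/sigma/tau, 10..12 k theta/sigma/tau,
# 13..15 na m theta/sigma/tau, 16..17 na h theta/sigma,
# 18..21 na tau_h (base, amplitude, theta, sigma), 22 h exponent

def pack_axon_kinetics(p: dict, kind: str = "main") -> np.ndarray:
    """Kinetics array for main-axon (AIS/node/internode) or collateral
    compartments; they differ only in the Na inactivation gate."""
    a = p["axon"]
    if kind == "collateral":
        th, sh = a["na_theta_h_collateral"], a["na_sigma_h_collateral"]
        tau_h1 = a["na_tau_h1_collateral"]
        h_pow = 1.0
    else:
        th, sh = a["na_theta_h"], a["na_sigma_h"]
        tau_h1 = a["na_tau_h1"]
        h_pow = a.get("na_h_power", 1.0)
    return np.array([a["e_na"], a["e_k"], a["e_leak"], 0.0,
                     a["kd_theta_a"], a["kd_sigma_a"], a["kd_tau_a"],
                     a["kd_theta_b"], a["kd_sigma_b"], a["kd_tau_b"],
                     a["k_theta"], a["k_sigma"], a["k_tau"],
                     a["na_theta_m"], a["na_sigma_m"], a["na_tau_m"],
                     th, sh,
                     a["na_tau_h0"], tau_h1,
                     a["na_tau_h_theta"], a["na_tau_h_sigma"], h_pow],
                    dtype=np.float64)


@njit(cache=True)
def axon_gate_rates(v, kin):
    """Return (am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b).

    Na+ uses node-type sigmoid gating: fast activation m and an
    inactivation gate h with half-inactivation below rest, which leaves
    no persistent Na+ window at depolarized potentials; the fast
    rectifier is a first-order sigmoid gate that repolarizes the spike;
    Kd is the low-threshold, slowly inactivating D-type current.
    """
    m_inf = 1.0 / (1.0 + math.exp(-(v - kin[13]) / kin[14]))
    am = m_inf / kin[15]
    bm = (1.0 - m_inf) / kin[15]
    h_inf = 1.0 / (1.0 + math.exp(-(v - kin[16]) / kin[17]))
    tau_h = kin[18] + kin[19] / (1.0 + math.exp((v - kin[20]) / kin[21]))
    ah = h_inf / tau_h
    bh = (1.0 - h_inf) / tau_h
    # fast rectifier: first-order sigmoid gate
    n_inf = 1.0 / (1.0 + math.exp(-(v - kin[10]) / kin[11]))
    an = n_inf / kin[12]
    bn = (1.0 - n_inf) / kin[12]
    a_inf = 1.0 / (1.0 + math.exp(-(v - kin[4]) / kin[5]))
    b_inf = 1.0 / (1.0 + math.exp(-(v - kin[7]) / kin[8]))
    return am, bm, ah, bh, an, bn, a_inf, kin[6], b_inf, kin[9]


@njit(cache=True)
def axon_rhs(y, g_na, g_k, g_kd, g_leak, cm, drive, kin):
    """dy/dt of one axon compartment [v, m, h, n, a, b].

    ``drive`` (uA/cm^2) is the sum of axial, extracellular-coupling and
    any injected current densities; conductances are the kind-resolved
    densities in mS/cm^2.
    """
    v, m, h, n, a, b = y[0], y[1], y[2], y[3], y[4], y[5]
    e_na, e_k, e_leak = kin[0], kin[1], kin[2]
    am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b = axon_gate_rates(v, kin)
    hh = h * h if kin[22] == 2.0 else h
    i_na = g_na * m * m * m * hh * (v - e_na)
    i_k = g_k * n * (v - e_k)
    i_kd = g_kd * a * b * (v - e_k)
    i_leak = g_leak * (v - e_leak)
    dy = np.empty(6)
    dy[0] = (-i_na - i_k - i_kd - i_leak + drive) / cm
    dy[1] = am * (1.0 - m) - bm * m
    dy[2] = ah * (1.0 - h) - bh * h
    dy[3] = an * (1.0 - n) - bn * n
    dy[4] = (a_inf - a) / tau_a
    dy[5] = (b_inf - b) / tau_b
    return dy


# ----------------------------------------------------------------------
# Interneuron (quadratic spiking model)

@njit(cache=True)
def izh_rhs(v, u, i_in, a, b):
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_in
    du = a * (b * v - u)
    return dv, du


# ----------------------------------------------------------------------
# STN neuron
#
# Parameter array layout (see pack_stn_params):
# 0 cm, 1 g_na, 2 e_na, 3 g_k, 4 e_k, 5 g_a, 6 g_l, 7 e_ca, 8 g_t,
# 9 g_cak, 10 g_leak, 11 e_leak,
# 12..13 theta/sigma m, 14..15 h, 16..17 n, 18..19 p, 20..21 q,
# 22..23 a, 24..25 b, 26..27 c, 28..29 d1, 30..31 d2(Ca), 32..33 r(Ca),
# 34 tau_d2, 35 tau_r, 36 ca_alpha, 37 ca_k, 38 i_app

_STN_KEYS = ("m", "h", "n", "p", "q", "a", "b", "c", "d1", "d2", "r")


def pack_stn_params(p: dict) -> np.ndarray:
    s = p["stn"]
    arr = [s["cm"], s["g_na"], s["e_na"], s["g_k"], s["e_k"], s["g_a"],
           s["g_l_ca"], s["e_ca"], s["g_t"], s["g_cak"], s["g_leak"],
           s["e_leak"]]
    for key in _STN_KEYS:
        arr += [s[f"theta_{key}"], s[f"sigma_{key}"]]
    arr += [s["tau_d2"], s["tau_r"], s["ca_alpha"], s["ca_k"], s["i_app"]]
    return np.array(arr, dtype=np.float64)


@njit(cache=True)
def _sig(x, theta, sigma):
    return 1.0 / (1.0 + math.exp(-(x - theta) / sigma))


@njit(cache=True)
def stn_taus(v):
    """Voltage-dependent time constants (ms) of the STN gates."""
    tau_m = 0.2 + 3.0 / (1.0 + math.exp((v + 53.0) / 0.7))
    tau_h = 24.5 / (math.exp((v + 50.0) / 15.0) + math.exp(-(v + 50.0) / 16.0))
    tau_n = 11.0 / (math.exp((v + 40.0) / 40.0) + math.exp(-(v + 40.0) / 50.0))
    tau_p = 5.0 + 0.33 / (math.exp((v + 27.0) / 10.0)
                          + math.exp(-(v + 102.0) / 15.0))
    tau_q = 400.0 / (math.exp((v + 50.0) / 15.0) + math.exp(-(v + 50.0) / 16.0))
    tau_a = 1.0 + 1.0 / (1.0 + math.exp((v + 40.0) / 0.5))
    tau_b = 200.0 / (math.exp((v + 60.0) / 30.0) + math.exp(-(v + 40.0) / 10.0))
    tau_c = 45.0 + 10.0 / (math.exp((v + 27.0) / 20.0)
                           + math.exp(-(v + 50.0) / 15.0))
    tau_d1 = 400.0 + 500.0 / (math.exp((v + 40.0) / 15.0)
                              + math.exp(-(v + 20.0) / 20.0))
    return tau_m, tau_h, tau_n, tau_p, tau_q, tau_a, tau_b, tau_c, tau_d1


@njit(cache=True)
def stn_rhs(y, i_syn, pp):
    """dy/dt of the STN state [v,m,h,n,a,b,c,d1,d2,p,q,r,ca].

    ``i_syn`` is the total synaptic current density (outward positive,
    uA/cm^2); calcium (uM) follows influx through I_L and I_T.
    """
    v = y[0]
    m, h, n = y[1], y[2], y[3]
    a, b, c, d1, d2 = y[4], y[5], y[6], y[7], y[8]
    p, q, r, ca = y[9], y[10], y[11], y[12]
    cm = pp[0]
    i_na = pp[1] * m * m * m * h * (v - pp[2])
    i_k = pp[3] * n * n * n * n * (v - pp[4])
    i_a = pp[5] * a * a * b * (v - pp[4])
    i_l = pp[6] * c * c * d1 * d2 * (v - pp[7])
    i_t = pp[8] * p * p * q * (v - pp[7])
    i_cak = pp[9] * r * r * (v - pp[4])
    i_leak = pp[10] * (v - pp[11])
    tau_m, tau_h, tau_n, tau_p, tau_q, tau_a, tau_b, tau_c, tau_d1 = stn_taus(v)
    dy = np.empty(13)
    dy[0] = (-i_na - i_k - i_a - i_l - i_t - i_cak - i_leak
             - i_syn + pp[38]) / cm
    dy[1] = (_sig(v, pp[12], pp[13]) - m) / tau_m
    dy[2] = (_sig(v, pp[14], pp[15]) - h) / tau_h
    dy[3] = (_sig(v, pp[16], pp[17]) - n) / tau_n
    dy[4] = (_sig(v, pp[22], pp[23]) - a) / tau_a
    dy[5] = (_sig(v, pp[24], pp[25]) - b) / tau_b
    dy[6] = (_sig(v, pp[26], pp[27]) - c) / tau_c
    dy[7] = (_sig(v, pp[28], pp[29]) - d1) / tau_d1
    dy[8] = (_sig(ca, pp[30], pp[31]) - d2) / pp[34]
    dy[9] = (_sig(v, pp[18], pp[19]) - p) / tau_p
    dy[10] = (_sig(v, pp[20], pp[21]) - q) / tau_q
    dy[11] = (_sig(ca, pp[32], pp[33]) - r) / pp[35]
    dy[12] = -pp[36] * (i_l + i_t) - pp[37] * ca
    return dy


# ----------------------------------------------------------------------
# GPe neuron
#
# Parameter array layout (see pack_gpe_params):
# 0 cm, 1 g_l, 2 v_l, 3 g_k, 4 v_k, 5 g_na, 6 v_na, 7 g_t, 8 g_ca,
# 9 v_ca, 10 g_ahp, 11..12 theta/sigma m, 13..14 h, 15..16 n, 17..18 r,
# 19..20 a, 21..22 s, 23 tau_h0, 24 tau_h1, 25 theta_h_tau, 26 sigma_h_tau,
# 27 tau_n0, 28 tau_n1, 29 theta_n_tau, 30 sigma_n_tau, 31 phi_h,
# 32 phi_n, 33 phi_r, 34 tau_r, 35 k1_ahp, 36 ca_eps, 37 ca_k, 38 i_app

def pack_gpe_params(p: dict) -> np.ndarray:
    g = p["gpe"]
    arr = [g["cm"], g["g_l"], g["v_l"], g["g_k"], g["v_k"], g["g_na"],
           g["v_na"], g["g_t"], g["g_ca"], g["v_ca"], g["g_ahp"]]
    for key in ("m", "h", "n", "r", "a", "s"):
        arr += [g[f"theta_{key}"], g[f"sigma_{key}"]]
    arr += [g["tau_h0"], g["tau_h1"], g["theta_h_tau"], g["sigma_h_tau"],
            g["tau_n0"], g["tau_n1"], g["theta_n_tau"], g["sigma_n_tau"],
            g["phi_h"], g["phi_n"], g["phi_r"], g["tau_r"], g["k1_ahp"],
            g["ca_eps"], g["ca_k"], g["i_app"]]
    return np.array(arr, dtype=np.float64)


@njit(cache=True)
def gpe_rhs(y, i_syn, pp):
    """dy/dt of the GPe state [v, h, n, r, ca]; i_syn outward positive."""
    v, h, n, r, ca = y[0], y[1], y[2], y[3], y[4]
    m_inf = _sig(v, pp[11], pp[12])
    a_inf = _sig(v, pp[19], pp[20])
    s_inf = _sig(v, pp[21], pp[22])
    i_l = pp[1] * (v - pp[2])
    i_k = pp[3] * n * n * n * n * (v - pp[4])
    i_na = pp[5] * m_inf * m_inf * m_inf * h * (v - pp[6])
    i_t = pp[7] * a_inf * a_inf * a_inf * r * (v - pp[9])
    i_ca = pp[8] * s_inf * s_inf * (v - pp[9])
    i_ahp = pp[10] * (v - pp[4]) * ca / (ca + pp[35])
    tau_h = pp[23] + pp[24] / (1.0 + math.exp(-(v - pp[25]) / pp[26]))
    tau_n = pp[27] + pp[28] / (1.0 + math.exp(-(v - pp[29]) / pp[30]))
    dy = np.empty(5)
    dy[0] = (-i_l - i_k - i_na - i_t - i_ca - i_ahp - i_syn + pp[38]) / pp[0]
    dy[1] = pp[31] * (_sig(v, pp[13], pp[14]) - h) / tau_h
    dy[2] = pp[32] * (_sig(v, pp[15], pp[16]) - n) / tau_n
    dy[3] = pp[33] * (_sig(v, pp[17], pp[18]) - r) / pp[34]
    dy[4] = pp[36] * (-i_ca - i_t - pp[37] * ca)
    return dy


# ----------------------------------------------------------------------
# Steady-state initializers (gates at their resting equilibrium)

def soma_init(pp: np.ndarray, v0: float | None = None) -> np.ndarray:
    """Soma state at rest; by default Vm solves the zero-current fixed
    point with all gates at steady state."""
    if v0 is None:
        def net_current(v):
            y = soma_init(pp, v)
            return soma_rhs(y, 0.0, pp)[0]
        lo, hi = -90.0, -55.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if net_current(mid) > 0:
                lo = mid   # still depolarizing -> fixed point is above
            else:
                hi = mid
        v0 = 0.5 * (lo + hi)
    am, bm, ah, bh, an, bn, p_inf, _ = soma_gate_rates(v0, pp[9], pp[6])
    return np.array([v0, am / (am + bm), ah / (ah + bh), an / (an + bn),
                     p_inf])


def axon_init(kin: np.ndarray, v0: float = -70.0) -> np.ndarray:
    am, bm, ah, bh, an, bn, a_inf, _, b_inf, _ = axon_gate_rates(v0, kin)
    return np.array([v0, am / (am + bm), ah / (ah + bh), an / (an + bn),
                     a_inf, b_inf])


def stn_init(pp: np.ndarray, v0: float = -58.0, ca0: float = 0.05) -> np.ndarray:
    y = np.empty(STN_NSTATE)
    y[0] = v0
    y[1] = _sig(v0, pp[12], pp[13])
    y[2] = _sig(v0, pp[14], pp[15])
    y[3] = _sig(v0, pp[16], pp[17])
    y[4] = _sig(v0, pp[22], pp[23])
    y[5] = _sig(v0, pp[24], pp[25])
    y[6] = _sig(v0, pp[26], pp[27])
    y[7] = _sig(v0, pp[28], pp[29])
    y[8] = _sig(ca0, pp[30], pp[31])
    y[9] = _sig(v0, pp[18], pp[19])
    y[10] = _sig(v0, pp[20], pp[21])
    y[11] = _sig(ca0, pp[32], pp[33])
    y[12] = ca0
    return y


def gpe_init(pp: np.ndarray, v0: float = -62.0, ca0: float = 0.1) -> np.ndarray:
    return np.array([v0, _sig(v0, pp[13], pp[14]), _sig(v0, pp[15], pp[16]),
                     _sig(v0, pp[17], pp[18]), ca0])


# ======================================================================
# Typed state API


def _check_finite(obj) -> None:
    for f in fields(obj):
        val = getattr(obj, f.name)
        if isinstance(val, (int, float)) and not math.isfinite(val):
            raise ValueError(f"non-finite state field {f.name!r} = {val!r}")


@dataclass
class CorticalSomaState:
    """Cortical soma state: membrane potential and HH gating variables."""
    vm: float = -71.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0
    p: float = 0.0
    cm: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.vm, self.m, self.h, self.n, self.p])


@dataclass
class AxonCompartmentState:
    """One axon compartment: potential, gating and compartment kind."""
    vm: float = -70.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0
    a: float = 0.0
    b: float = 1.0
    kind: str = "node"

    def as_array(self) -> np.ndarray:
        return np.array([self.vm, self.m, self.h, self.n, self.a, self.b])


@dataclass
class InterneuronState:
    """Quadratic spiking interneuron state and parameters."""
    vm: float = -65.0
    u: float = -13.0
    a: float = 0.1
    b: float = 0.2
    c: float = -65.0
    d: float = 2.0
    v_peak: float = 30.0


@dataclass
class STNState:
    """STN neuron state: potential, gating and intracellular Ca (uM)."""
    vm: float = -58.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0
    a: float = 0.0
    b: float = 1.0
    c: float = 0.0
    d1: float = 1.0
    d2: float = 1.0
    p: float = 0.0
    q: float = 1.0
    r: float = 0.0
    ca: float = 0.05
    cm: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.vm, self.m, self.h, self.n, self.a, self.b,
                         self.c, self.d1, self.d2, self.p, self.q, self.r,
                         self.ca])


@dataclass
class GPeState:
    """GPe neuron state: potential, gating and intracellular Ca."""
    vm: float = -62.0
    h: float = 1.0
    n: float = 0.0
    r: float = 0.0
    ca: float = 0.1
    cm: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.vm, self.h, self.n, self.r, self.ca])


@dataclass
class ChannelDensityTable:
    """Axonal channel densities (pS/um^2) per compartment kind."""
    g_na: dict
    g_k: dict
    g_kd: dict
    g_leak: float = 0.23

    @classmethod
    def from_params(cls, p: dict) -> "ChannelDensityTable":
        a = p["axon"]
        return cls(g_na=dict(a["g_na_ps_um2"]), g_k=dict(a["g_k_ps_um2"]),
                   g_kd=dict(a["g_kd_ps_um2"]), g_leak=a["g_leak_ps_um2"])

    def row(self, kind: str) -> tuple[float, float, float, float]:
        """Densities (g_na, g_k, g_kd, g_leak) in mS/cm^2 for one kind."""
        if kind not in AXON_KINDS:
            raise ValueError(
                f"unknown compartment kind {kind!r}; expected one of {AXON_KINDS}")
        return (0.1 * self.g_na[kind], 0.1 * self.g_k[kind],
                0.1 * self.g_kd[kind], 0.1 * self.g_leak)


# ----------------------------------------------------------------------
# Spec-level derivative operations


def soma_derivatives(state: CorticalSomaState, i_syn: float = 0.0,
                     i_inj: float = 0.0, params: dict | None = None
                     ) -> np.ndarray:
    """Time derivatives of the cortical soma state.

    ``i_syn`` is the synaptic current (outward positive) and ``i_inj``
    an injected current (inward positive), both in uA/cm^2.
    """
    _check_finite(state)
    if not (math.isfinite(i_syn) and math.isfinite(i_inj)):
        raise ValueError("non-finite input current")
    from .params import default_params
    pp = pack_soma_params(params or default_params())
    pp = pp.copy()
    pp[0] = state.cm
    return soma_rhs(state.as_array(), i_inj - i_syn, pp)


def axon_derivatives(state: AxonCompartmentState,
                     densities: ChannelDensityTable,
                     drive: float = 0.0, params: dict | None = None,
                     cm: float | None = None) -> np.ndarray:
    """Time derivatives of one axon compartment.

    The ionic term uses the density row of the compartment's ``kind``;
    ``drive`` (axial + extracellular coupling, uA/cm^2) is added to
    dVm/dt.
    """
    _check_finite(state)
    g_na, g_k, g_kd, g_leak = densities.row(state.kind)
    from .params import default_params
    p = params or default_params()
    kin = pack_axon_kinetics(
        p, kind="collateral" if state.kind == "collateral" else "main")
    if cm is None:
        cm = p["axon"]["cm"]
        if state.kind == "internode":
            f = p["axon"]["myelin_factor"]
            cm /= f
            g_na /= f
            g_k /= f
            g_kd /= f
            g_leak /= f
    return axon_rhs(state.as_array(), g_na, g_k, g_kd, g_leak, cm, drive, kin)


def interneuron_step(state: InterneuronState, i_input: float, dt: float
                     ) -> tuple[InterneuronState, bool]:
    """Advance the interneuron one step of ``dt`` ms; returns (state, spiked).

    The quadratic membrane update is applied first and the after-spike
    reset rule checked afterwards: whenever Vm reaches ``v_peak`` the
    potential is reset to ``c`` and the recovery variable incremented by
    exactly ``d``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(i_input):
        raise ValueError("non-finite input current")
    _check_finite(state)
    v, u = state.vm, state.u
    # RK4 on the continuous part
    k1v, k1u = izh_rhs(v, u, i_input, state.a, state.b)
    k2v, k2u = izh_rhs(v + 0.5 * dt * k1v, u + 0.5 * dt * k1u, i_input,
                       state.a, state.b)
    k3v, k3u = izh_rhs(v + 0.5 * dt * k2v, u + 0.5 * dt * k2u, i_input,
                       state.a, state.b)
    k4v, k4u = izh_rhs(v + dt * k3v, u + dt * k3u, i_input, state.a, state.b)
    v += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
    u += dt * (k1u + 2 * k2u + 2 * k3u + k4u) / 6.0
    spiked = v >= state.v_peak
    if spiked:
        v = state.c
        u = u + state.d
    out = InterneuronState(vm=v, u=u, a=state.a, b=state.b, c=state.c,
                           d=state.d, v_peak=state.v_peak)
    return out, bool(spiked)


def stn_derivatives(state: STNState, i_syn: float = 0.0,
                    params: dict | None = None) -> np.ndarray:
    """Time derivatives of the STN state (i_syn outward positive)."""
    _check_finite(state)
    if state.ca < 0:
        raise ValueError(f"negative Ca concentration: {state.ca}")
    from .params import default_params
    pp = pack_stn_params(params or default_params())
    pp = pp.copy()
    pp[0] = state.cm
    return stn_rhs(state.as_array(), i_syn, pp)


def gpe_derivatives(state: GPeState, i_syn: float = 0.0,
                    params: dict | None = None) -> np.ndarray:
    """Time derivatives of the GPe state (i_syn outward positive)."""
    _check_finite(state)
    if state.ca < 0:
        raise ValueError(f"negative Ca concentration: {state.ca}")
    from .params import default_params
    pp = pack_gpe_params(params or default_params())
    pp = pp.copy()
    pp[0] = state.cm
    return gpe_rhs(state.as_array(), i_syn, pp)
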
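"""Compiled fixed-step RK4 integration kernel for the full network.

All continuous states (cortical cable compartments, STN, GPe,
interneurons, alpha-synapse states) advance with classical RK4 at a
fixed step.  Voltage-dependent gating rates of the cable compartments
are evaluated through dense lookup tables (built from the exact rate
functions in :mod:`dbsnet.neurons`); point-neuron rates are evaluated
directly.  The stimulus is held piecewise-constant over each step with
pulse edges aligned to the step grid.

Alpha-function synapses are integrated exactly: each pathway keeps a
pair (s, z) obeying z' = -z/tau, s' = -s/tau + z, so that an impulse
z += e/tau at a presynaptic spike produces the conductance factor
((t - t0)/tau) exp(1 - (t - t0)/tau) with unit peak.

Spikes are upward crossings of the detection threshold with a refractory
lockout per detector.  The interneuron after-spike reset is applied
after each RK4 step.  Gaussian current noise is added to each neuron's
membrane potential after each step with Euler-Maruyama sqrt(dt) scaling.
"""

import math

import numpy as np
from numba import njit

E_CONST = math.e

# status codes
OK = 0
DIVERGED = 1
OVERFLOW = 2


@njit(cache=True)
def _cx_rhs(Vc, Gc, dV, dG,
            n_cx, C, kinds,
            areas, cmc, gna, gk, gkd, gleak, eleak,
            soma_AB, axon_AB, coll_AB,
            vmin, inv_dv, ngrid,
            e_na, e_k, s_ic_val, g_ic, e_ic,
            beta_amp, beta_phase, omega, t):
    """Derivatives of the local (membrane) cortical cable states at one
    RK4 stage.  Axial and extracellular coupling are handled by the
    implicit linear step, not here."""
    for n in range(n_cx):
        # soma (compartment 0)
        v = Vc[n, 0]
        x = (v - vmin) * inv_dv
        i = int(x)
        if i < 0:
            i = 0
            x = 0.0
        elif i > ngrid - 2:
            i = ngrid - 2
            x = float(ngrid - 1)
        f = x - i
        m = Gc[n, 0, 0]
        h = Gc[n, 0, 1]
        nn = Gc[n, 0, 2]
        pg = Gc[n, 0, 3]
        for g in range(4):
            A = soma_AB[i, 2 * g] + f * (soma_AB[i + 1, 2 * g]
                                         - soma_AB[i, 2 * g])
            B = soma_AB[i, 2 * g + 1] + f * (soma_AB[i + 1, 2 * g + 1]
                                             - soma_AB[i, 2 * g + 1])
            dG[n, 0, g] = A - B * Gc[n, 0, g]
        dG[n, 0, 4] = 0.0
        i_ion = (gna[0] * m * m * m * h * (v - e_na)
                 + gk[0] * nn * nn * nn * nn * (v - e_k)
                 + gkd[0] * pg * (v - e_k)
                 + gleak[0] * (v - eleak[0]))
        i_beta = beta_amp[n] * math.sin(omega * t + beta_phase[n])
        if i_beta < 0.0:
            i_beta = 0.0
        i_syn = g_ic * (v - e_ic) * s_ic_val
        dV[n, 0] = (-i_ion - i_syn + i_beta) / cmc[0]
        # axon compartments
        for c in range(1, C):
            v = Vc[n, c]
            x = (v - vmin) * inv_dv
            i = int(x)
            if i < 0:
                i = 0
                x = 0.0
            elif i > ngrid - 2:
                i = ngrid - 2
                x = float(ngrid - 1)
            f = x - i
            m = Gc[n, c, 0]
            h = Gc[n, c, 1]
            nn = Gc[n, c, 2]
            ag = Gc[n, c, 3]
            bg = Gc[n, c, 4]
            tbl = coll_AB if kinds[c] == 4 else axon_AB
            for g in range(5):
                A = tbl[i, 2 * g] + f * (tbl[i + 1, 2 * g] - tbl[i, 2 * g])
                B = tbl[i, 2 * g + 1] + f * (tbl[i + 1, 2 * g + 1]
                                             - tbl[i, 2 * g + 1])
                dG[n, c, g] = A - B * Gc[n, c, g]
            i_ion = (gna[c] * m * m * m * h * (v - e_na)
                     + gk[c] * nn * (v - e_k)
                     + gkd[c] * ag * bg * (v - e_k)
                     + gleak[c] * (v - eleak[c]))
            dV[n, c] = -i_ion / cmc[c]


@njit(cache=True)
def _stn_pop_rhs(Y, dY, s_cs, s_gs, pp, g_cs, g_gs, e_gs, n_stn):
    for idx in range(n_stn):
        v = Y[idx, 0]
        m = Y[idx, 1]
        h = Y[idx, 2]
        n = Y[idx, 3]
        a = Y[idx, 4]
        b = Y[idx, 5]
        c = Y[idx, 6]
        d1 = Y[idx, 7]
        d2 = Y[idx, 8]
        p = Y[idx, 9]
        q = Y[idx, 10]
        r = Y[idx, 11]
        ca = Y[idx, 12]
        i_na = pp[1] * m * m * m * h * (v - pp[2])
        i_k = pp[3] * n * n * n * n * (v - pp[4])
        i_a = pp[5] * a * a * b * (v - pp[4])
        i_l = pp[6] * c * c * d1 * d2 * (v - pp[7])
        i_t = pp[8] * p * p * q * (v - pp[7])
        i_cak = pp[9] * r * r * (v - pp[4])
        i_leak = pp[10] * (v - pp[11])
        i_syn = g_cs * v * s_cs[idx] + g_gs * (v - e_gs) * s_gs[idx]
        tau_m = 0.2 + 3.0 / (1.0 + math.exp((v + 53.0) / 0.7))
        tau_h = 24.5 / (math.exp((v + 50.0) / 15.0)
                        + math.exp(-(v + 50.0) / 16.0))
        tau_n = 11.0 / (math.exp((v + 40.0) / 40.0)
                        + math.exp(-(v + 40.0) / 50.0))
        tau_p = 5.0 + 0.33 / (math.exp((v + 27.0) / 10.0)
                              + math.exp(-(v + 102.0) / 15.0))
        tau_q = 400.0 / (math.exp((v + 50.0) / 15.0)
                         + math.exp(-(v + 50.0) / 16.0))
        tau_a = 1.0 + 1.0 / (1.0 + math.exp((v + 40.0) / 0.5))
        tau_b = 200.0 / (math.exp((v + 60.0) / 30.0)
                         + math.exp(-(v + 40.0) / 10.0))
        tau_c = 45.0 + 10.0 / (math.exp((v + 27.0) / 20.0)
                               + math.exp(-(v + 50.0) / 15.0))
        tau_d1 = 400.0 + 500.0 / (math.exp((v + 40.0) / 15.0)
                                  + math.exp(-(v + 20.0) / 20.0))
        dY[idx, 0] = (-i_na - i_k - i_a - i_l - i_t - i_cak - i_leak
                      - i_syn + pp[38]) / pp[0]
        dY[idx, 1] = (1.0 / (1.0 + math.exp(-(v - pp[12]) / pp[13])) - m) / tau_m
        dY[idx, 2] = (1.0 / (1.0 + math.exp(-(v - pp[14]) / pp[15])) - h) / tau_h
        dY[idx, 3] = (1.0 / (1.0 + math.exp(-(v - pp[16]) / pp[17])) - n) / tau_n
        dY[idx, 4] = (1.0 / (1.0 + math.exp(-(v - pp[22]) / pp[23])) - a) / tau_a
        dY[idx, 5] = (1.0 / (1.0 + math.exp(-(v - pp[24]) / pp[25])) - b) / tau_b
        dY[idx, 6] = (1.0 / (1.0 + math.exp(-(v - pp[26]) / pp[27])) - c) / tau_c
        dY[idx, 7] = (1.0 / (1.0 + math.exp(-(v - pp[28]) / pp[29])) - d1) / tau_d1
        dY[idx, 8] = (1.0 / (1.0 + math.exp(-(ca - pp[30]) / pp[31])) - d2) / pp[34]
        dY[idx, 9] = (1.0 / (1.0 + math.exp(-(v - pp[18]) / pp[19])) - p) / tau_p
        dY[idx, 10] = (1.0 / (1.0 + math.exp(-(v - pp[20]) / pp[21])) - q) / tau_q
        dY[idx, 11] = (1.0 / (1.0 + math.exp(-(ca - pp[32]) / pp[33])) - r) / pp[35]
        dY[idx, 12] = -pp[36] * (i_l + i_t) - pp[37] * ca


@njit(cache=True)
def _gpe_pop_rhs(Y, dY, s_sg, s_gg, pp, g_sg, g_gg, e_gg, n_gpe):
    for idx in range(n_gpe):
        v = Y[idx, 0]
        h = Y[idx, 1]
        n = Y[idx, 2]
        r = Y[idx, 3]
        ca = Y[idx, 4]
        m_inf = 1.0 / (1.0 + math.exp(-(v - pp[11]) / pp[12]))
        a_inf = 1.0 / (1.0 + math.exp(-(v - pp[19]) / pp[20]))
        s_inf = 1.0 / (1.0 + math.exp(-(v - pp[21]) / pp[22]))
        i_l = pp[1] * (v - pp[2])
        i_k = pp[3] * n * n * n * n * (v - pp[4])
        i_na = pp[5] * m_inf * m_inf * m_inf * h * (v - pp[6])
        i_t = pp[7] * a_inf * a_inf * a_inf * r * (v - pp[9])
        i_ca = pp[8] * s_inf * s_inf * (v - pp[9])
        i_ahp = pp[10] * (v - pp[4]) * ca / (ca + pp[35])
        i_syn = g_sg * v * s_sg[idx] + g_gg * (v - e_gg) * s_gg[idx]
        tau_h = pp[23] + pp[24] / (1.0 + math.exp(-(v - pp[25]) / pp[26]))
        tau_n = pp[27] + pp[28] / (1.0 + math.exp(-(v - pp[29]) / pp[30]))
        dY[idx, 0] = (-i_l - i_k - i_na - i_t - i_ca - i_ahp - i_syn
                      + pp[38]) / pp[0]
        dY[idx, 1] = pp[31] * (1.0 / (1.0 + math.exp(-(v - pp[13]) / pp[14]))
                               - h) / tau_h
        dY[idx, 2] = pp[32] * (1.0 / (1.0 + math.exp(-(v - pp[15]) / pp[16]))
                               - n) / tau_n
        dY[idx, 3] = pp[33] * (1.0 / (1.0 + math.exp(-(v - pp[17]) / pp[18]))
                               - r) / pp[34]
        dY[idx, 4] = pp[36] * (-i_ca - i_t - pp[37] * ca)


@njit(cache=True)
def run_network(
        # grid
        n_steps, dt, t0, seed,
        stim_active, in_drive_active, i_amp, in_drive_amp, in_jitter,
        mode,
        # cortex cable (state mutated in place)
        Vc, Gc, kinds, areas, cmc, gna, gk, gkd, gleak, eleak,
        Minv, gstim,
        soma_AB, axon_AB, coll_AB, vmin, inv_dv,
        e_na, e_k, term_idx, n10_idx, n9_idx,
        # beta drive
        beta_amp, beta_phase, beta_omega,
        # interneurons
        v_in, u_in, in_a, in_b, in_c, in_d, in_vpeak,
        # STN / GPe
        Ystn, pp_stn, Ygpe, pp_gpe,
        # synapses (shared + per-post, mutated)
        syn_shared, tau_ci, tau_ic, g_ci, g_ic, e_ic,
        s_cs, z_cs, s_gs, z_gs, s_sg, z_sg, s_gg, z_gg,
        tau_cs, tau_gs, tau_sg, tau_gg,
        g_cs, g_gs, g_sg, g_gg, e_gs, e_gg,
        cs_targets, gs_ptr, gs_tgt, sg_targets, gg_ptr, gg_tgt,
        # antidromic-mode event relay
        relay_steps, pending, dir_win,
        # noise, detection
        sigma_noise, thr, lock_steps,
        # records
        rec_dec, rec_cx, rec_in, rec_stn, rec_gpe, rec_cable, cable_rec_id,
        cx_spk_id, cx_spk_t, in_spk_id, in_spk_t,
        stn_spk_id, stn_spk_t, gpe_spk_id, gpe_spk_t,
        term_spk_id, term_spk_t, counters, div_info):
    np.random.seed(seed)
    n_cx = Vc.shape[0]
    C = Vc.shape[1]
    n_in = v_in.shape[0]
    n_stn = Ystn.shape[0]
    n_gpe = Ygpe.shape[0]
    ngrid = soma_AB.shape[0]

    # RK4 work arrays
    kV1 = np.empty((n_cx, C))
    kV2 = np.empty((n_cx, C))
    kV3 = np.empty((n_cx, C))
    kV4 = np.empty((n_cx, C))
    kG1 = np.empty((n_cx, C, 5))
    kG2 = np.empty((n_cx, C, 5))
    kG3 = np.empty((n_cx, C, 5))
    kG4 = np.empty((n_cx, C, 5))
    Vt = np.empty((n_cx, C))
    Gt = np.empty((n_cx, C, 5))
    vrow = np.empty(C)
    kS1 = np.empty((n_stn, 13))
    kS2 = np.empty((n_stn, 13))
    kS3 = np.empty((n_stn, 13))
    kS4 = np.empty((n_stn, 13))
    St = np.empty((n_stn, 13))
    kP1 = np.empty((n_gpe, 5))
    kP2 = np.empty((n_gpe, 5))
    kP3 = np.empty((n_gpe, 5))
    kP4 = np.empty((n_gpe, 5))
    Pt = np.empty((n_gpe, 5))
    s_cs_h = np.empty(n_stn)
    s_cs_1 = np.empty(n_stn)
    s_gs_h = np.empty(n_stn)
    s_gs_1 = np.empty(n_stn)
    s_sg_h = np.empty(n_gpe)
    s_sg_1 = np.empty(n_gpe)
    s_gg_h = np.empty(n_gpe)
    s_gg_1 = np.empty(n_gpe)

    # detector state
    prev_cx = np.empty(n_cx)
    prev_term = np.empty(n_cx)
    prev_n10 = np.empty(n_cx)
    prev_n9 = np.empty(n_cx)
    lock_cx = np.zeros(n_cx, dtype=np.int64)
    lock_term = np.zeros(n_cx, dtype=np.int64)
    lock_n10 = np.zeros(n_cx, dtype=np.int64)
    lock_n9 = np.zeros(n_cx, dtype=np.int64)
    last_n9 = np.full(n_cx, -1e18)
    prev_stn = np.empty(n_stn)
    lock_stn = np.zeros(n_stn, dtype=np.int64)
    prev_gpe = np.empty(n_gpe)
    lock_gpe = np.zeros(n_gpe, dtype=np.int64)
    for n in range(n_cx):
        prev_cx[n] = Vc[n, 0]
        prev_term[n] = Vc[n, term_idx]
        prev_n10[n] = Vc[n, n10_idx]
        prev_n9[n] = Vc[n, n9_idx]
    for i in range(n_stn):
        prev_stn[i] = Ystn[i, 0]
    for i in range(n_gpe):
        prev_gpe[i] = Ygpe[i, 0]

    # synapse decay factors
    eh_ci = math.exp(-0.5 * dt / tau_ci)
    e1_ci = math.exp(-dt / tau_ci)
    eh_ic = math.exp(-0.5 * dt / tau_ic)
    e1_ic = math.exp(-dt / tau_ic)
    eh_cs = math.exp(-0.5 * dt / tau_cs)
    e1_cs = math.exp(-dt / tau_cs)
    eh_gs = math.exp(-0.5 * dt / tau_gs)
    e1_gs = math.exp(-dt / tau_gs)
    eh_sg = math.exp(-0.5 * dt / tau_sg)
    e1_sg = math.exp(-dt / tau_sg)
    eh_gg = math.exp(-0.5 * dt / tau_gg)
    e1_gg = math.exp(-dt / tau_gg)
    kick_ci = E_CONST / tau_ci
    kick_ic = E_CONST / tau_ic
    kick_cs = E_CONST / tau_cs
    kick_gs = E_CONST / tau_gs
    kick_sg = E_CONST / tau_sg
    kick_gg = E_CONST / tau_gg

    noise_fac = sigma_noise * math.sqrt(dt)
    half = 0.5 * dt
    sixth = dt / 6.0
    ring = relay_steps + 1
    K_cs = cs_targets.shape[1]
    K_sg = sg_targets.shape[1]
    rec_rows_cx = rec_cx.shape[0]
    rec_rows_cable = rec_cable.shape[0]
    rec_rows_in = rec_in.shape[0]
    rec_rows_stn = rec_stn.shape[0]
    rec_rows_gpe = rec_gpe.shape[0]

    for step in range(n_steps):
        t = t0 + step * dt
        istim = i_amp if stim_active[step] == 1 else 0.0

        # record (state at time t)
        if step % rec_dec == 0:
            row = step // rec_dec
            if row < rec_rows_cx:
                for n in range(n_cx):
                    rec_cx[row, n] = Vc[n, 0]
            if row < rec_rows_cable:
                for c in range(C):
                    rec_cable[row, c] = Vc[cable_rec_id, c]
            if row < rec_rows_in:
                for n in range(n_in):
                    rec_in[row, n] = v_in[n]
            if row < rec_rows_stn:
                for i in range(n_stn):
                    rec_stn[row, i] = Ystn[i, 0]
            if row < rec_rows_gpe:
                for i in range(n_gpe):
                    rec_gpe[row, i] = Ygpe[i, 0]

        # shared synapse values at the three stage times
        s_ci = syn_shared[0]
        z_ci = syn_shared[1]
        s_ic = syn_shared[2]
        z_ic = syn_shared[3]
        s_ci_h = (s_ci + half * z_ci) * eh_ci
        s_ci_1 = (s_ci + dt * z_ci) * e1_ci
        s_ic_h = (s_ic + half * z_ic) * eh_ic
        s_ic_1 = (s_ic + dt * z_ic) * e1_ic
        for i in range(n_stn):
            s_cs_h[i] = (s_cs[i] + half * z_cs[i]) * eh_cs
            s_cs_1[i] = (s_cs[i] + dt * z_cs[i]) * e1_cs
            s_gs_h[i] = (s_gs[i] + half * z_gs[i]) * eh_gs
            s_gs_1[i] = (s_gs[i] + dt * z_gs[i]) * e1_gs
        for i in range(n_gpe):
            s_sg_h[i] = (s_sg[i] + half * z_sg[i]) * eh_sg
            s_sg_1[i] = (s_sg[i] + dt * z_sg[i]) * e1_sg
            s_gg_h[i] = (s_gg[i] + half * z_gg[i]) * eh_gg
            s_gg_1[i] = (s_gg[i] + dt * z_gg[i]) * e1_gg

        # ---- RK4 stage 1 (time t)
        _cx_rhs(Vc, Gc, kV1, kG1, n_cx, C, kinds,
                areas, cmc, gna, gk, gkd, gleak, eleak,
                soma_AB, axon_AB, coll_AB, vmin, inv_dv, ngrid,
                e_na, e_k, s_ic, g_ic, e_ic, beta_amp, beta_phase,
                beta_omega, t)
        _stn_pop_rhs(Ystn, kS1, s_cs, s_gs, pp_stn, g_cs, g_gs, e_gs, n_stn)
        _gpe_pop_rhs(Ygpe, kP1, s_sg, s_gg, pp_gpe, g_sg, g_gg, e_gg, n_gpe)

        # ---- stage 2 (t + dt/2)
        for n in range(n_cx):
            for c in range(C):
                Vt[n, c] = Vc[n, c] + half * kV1[n, c]
                for g in range(5):
                    Gt[n, c, g] = Gc[n, c, g] + half * kG1[n, c, g]
        _cx_rhs(Vt, Gt, kV2, kG2, n_cx, C, kinds,
                areas, cmc, gna, gk, gkd, gleak, eleak,
                soma_AB, axon_AB, coll_AB, vmin, inv_dv, ngrid,
                e_na, e_k, s_ic_h, g_ic, e_ic, beta_amp, beta_phase,
                beta_omega, t + half)
        for i in range(n_stn):
            for j in range(13):
                St[i, j] = Ystn[i, j] + half * kS1[i, j]
        _stn_pop_rhs(St, kS2, s_cs_h, s_gs_h, pp_stn, g_cs, g_gs, e_gs, n_stn)
        for i in range(n_gpe):
            for j in range(5):
                Pt[i, j] = Ygpe[i, j] + half * kP1[i, j]
        _gpe_pop_rhs(Pt, kP2, s_sg_h, s_gg_h, pp_gpe, g_sg, g_gg, e_gg, n_gpe)

        # ---- stage 3 (t + dt/2)
        for n in range(n_cx):
            for c in range(C):
                Vt[n, c] = Vc[n, c] + half * kV2[n, c]
                for g in range(5):
                    Gt[n, c, g] = Gc[n, c, g] + half * kG2[n, c, g]
        _cx_rhs(Vt, Gt, kV3, kG3, n_cx, C, kinds,
                areas, cmc, gna, gk, gkd, gleak, eleak,
                soma_AB, axon_AB, coll_AB, vmin, inv_dv, ngrid,
                e_na, e_k, s_ic_h, g_ic, e_ic, beta_amp, beta_phase,
                beta_omega, t + half)
        for i in range(n_stn):
            for j in range(13):
                St[i, j] = Ystn[i, j] + half * kS2[i, j]
        _stn_pop_rhs(St, kS3, s_cs_h, s_gs_h, pp_stn, g_cs, g_gs, e_gs, n_stn)
        for i in range(n_gpe):
            for j in range(5):
                Pt[i, j] = Ygpe[i, j] + half * kP2[i, j]
        _gpe_pop_rhs(Pt, kP3, s_sg_h, s_gg_h, pp_gpe, g_sg, g_gg, e_gg, n_gpe)

        # ---- stage 4 (t + dt)
        for n in range(n_cx):
            for c in range(C):
                Vt[n, c] = Vc[n, c] + dt * kV3[n, c]
                for g in range(5):
                    Gt[n, c, g] = Gc[n, c, g] + dt * kG3[n, c, g]
        _cx_rhs(Vt, Gt, kV4, kG4, n_cx, C, kinds,
                areas, cmc, gna, gk, gkd, gleak, eleak,
                soma_AB, axon_AB, coll_AB, vmin, inv_dv, ngrid,
                e_na, e_k, s_ic_1, g_ic, e_ic, beta_amp, beta_phase,
                beta_omega, t + dt)
        for i in range(n_stn):
            for j in range(13):
                St[i, j] = Ystn[i, j] + dt * kS3[i, j]
        _stn_pop_rhs(St, kS4, s_cs_1, s_gs_1, pp_stn, g_cs, g_gs, e_gs, n_stn)
        for i in range(n_gpe):
            for j in range(5):
                Pt[i, j] = Ygpe[i, j] + dt * kP3[i, j]
        _gpe_pop_rhs(Pt, kP4, s_sg_1, s_gg_1, pp_gpe, g_sg, g_gg, e_gg, n_gpe)

        # ---- combine, then the implicit (backward-Euler) axial +
        # extracellular coupling step: V <- Minv (V + dt C^-1 f istim)
        for n in range(n_cx):
            for c in range(C):
                Vc[n, c] += sixth * (kV1[n, c] + 2.0 * kV2[n, c]
                                     + 2.0 * kV3[n, c] + kV4[n, c])
                for g in range(5):
                    x = Gc[n, c, g] + sixth * (
                        kG1[n, c, g] + 2.0 * kG2[n, c, g]
                        + 2.0 * kG3[n, c, g] + kG4[n, c, g])
                    if x < 0.0:
                        x = 0.0
                    elif x > 1.0:
                        x = 1.0
                    Gc[n, c, g] = x
            for c in range(C):
                acc = gstim[n, c] * istim
                for c2 in range(C):
                    acc += Minv[c, c2] * Vc[n, c2]
                vrow[c] = acc
            for c in range(C):
                Vc[n, c] = vrow[c]
        for i in range(n_stn):
            for j in range(13):
                Ystn[i, j] += sixth * (kS1[i, j] + 2.0 * kS2[i, j]
                                       + 2.0 * kS3[i, j] + kS4[i, j])
            for j in range(1, 12):
                if Ystn[i, j] < 0.0:
                    Ystn[i, j] = 0.0
                elif Ystn[i, j] > 1.0:
                    Ystn[i, j] = 1.0
            if Ystn[i, 12] < 0.0:
                Ystn[i, 12] = 0.0
        for i in range(n_gpe):
            for j in range(5):
                Ygpe[i, j] += sixth * (kP1[i, j] + 2.0 * kP2[i, j]
                                       + 2.0 * kP3[i, j] + kP4[i, j])
            for j in range(1, 4):
                if Ygpe[i, j] < 0.0:
                    Ygpe[i, j] = 0.0
                elif Ygpe[i, j] > 1.0:
                    Ygpe[i, j] = 1.0
            if Ygpe[i, 4] < 0.0:
                Ygpe[i, 4] = 0.0

        # interneurons: RK4 on the quadratic model, then the reset rule
        n_in_spikes = 0
        for n in range(n_in):
            jstep = step - in_jitter[n]
            i_drive = in_drive_amp if (jstep >= 0
                                       and in_drive_active[jstep] == 1) \
                else 0.0
            v = v_in[n]
            u = u_in[n]
            i1 = i_drive - g_ci * v * s_ci
            k1v = 0.04 * v * v + 5.0 * v + 140.0 - u + i1
            k1u = in_a * (in_b * v - u)
            v2 = v + half * k1v
            u2 = u + half * k1u
            i2 = i_drive - g_ci * v2 * s_ci_h
            k2v = 0.04 * v2 * v2 + 5.0 * v2 + 140.0 - u2 + i2
            k2u = in_a * (in_b * v2 - u2)
            v3 = v + half * k2v
            u3 = u + half * k2u
            i3 = i_drive - g_ci * v3 * s_ci_h
            k3v = 0.04 * v3 * v3 + 5.0 * v3 + 140.0 - u3 + i3
            k3u = in_a * (in_b * v3 - u3)
            v4 = v + dt * k3v
            u4 = u + dt * k3u
            i4 = i_drive - g_ci * v4 * s_ci_1
            k4v = 0.04 * v4 * v4 + 5.0 * v4 + 140.0 - u4 + i4
            k4u = in_a * (in_b * v4 - u4)
            v += sixth * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            u += sixth * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
            if v >= in_vpeak:
                v = in_c
                u = u + in_d
                cnt = counters[1]
                if cnt < in_spk_id.shape[0]:
                    in_spk_id[cnt] = n
                    in_spk_t[cnt] = t + dt
                    counters[1] = cnt + 1
                else:
                    return OVERFLOW
                n_in_spikes += 1
            v_in[n] = v
            u_in[n] = u

        # exact alpha-synapse decay over the step; event kicks from
        # spikes detected at t + dt are added afterwards
        syn_shared[0] = (syn_shared[0] + dt * syn_shared[1]) * e1_ci
        syn_shared[1] = syn_shared[1] * e1_ci
        syn_shared[2] = (syn_shared[2] + dt * syn_shared[3]) * e1_ic
        syn_shared[3] = syn_shared[3] * e1_ic + n_in_spikes * kick_ic
        for i in range(n_stn):
            s_cs[i] = (s_cs[i] + dt * z_cs[i]) * e1_cs
            z_cs[i] = z_cs[i] * e1_cs
            s_gs[i] = (s_gs[i] + dt * z_gs[i]) * e1_gs
            z_gs[i] = z_gs[i] * e1_gs
        for i in range(n_gpe):
            s_sg[i] = (s_sg[i] + dt * z_sg[i]) * e1_sg
            z_sg[i] = z_sg[i] * e1_sg
            s_gg[i] = (s_gg[i] + dt * z_gg[i]) * e1_gg
            z_gg[i] = z_gg[i] * e1_gg

        # membrane noise (Euler-Maruyama additive current)
        if sigma_noise > 0.0:
            for n in range(n_cx):
                Vc[n, 0] += noise_fac * np.random.normal() / cmc[0]
            for n in range(n_in):
                v_in[n] += noise_fac * np.random.normal()
            for i in range(n_stn):
                Ystn[i, 0] += noise_fac * np.random.normal() / pp_stn[0]
            for i in range(n_gpe):
                Ygpe[i, 0] += noise_fac * np.random.normal() / pp_gpe[0]

        tnow = t + dt
        # antidromic-mode relay delivery
        if mode == 2:
            rp = step % ring
            for n in range(n_cx):
                if pending[rp, n] == 1:
                    pending[rp, n] = 0
                    for k in range(K_cs):
                        z_cs[cs_targets[n, k]] += kick_cs
                    cnt = counters[4]
                    if cnt < term_spk_id.shape[0]:
                        term_spk_id[cnt] = n
                        term_spk_t[cnt] = tnow
                        counters[4] = cnt + 1
                    else:
                        return OVERFLOW

        # spike detection
        for n in range(n_cx):
            v = Vc[n, 0]
            if lock_cx[n] > 0:
                lock_cx[n] -= 1
            elif prev_cx[n] < thr and v >= thr:
                lock_cx[n] = lock_steps
                cnt = counters[0]
                if cnt < cx_spk_id.shape[0]:
                    cx_spk_id[cnt] = n
                    cx_spk_t[cnt] = tnow
                    counters[0] = cnt + 1
                else:
                    return OVERFLOW
                syn_shared[1] += kick_ci       # cortex -> interneuron
            prev_cx[n] = v

            v = Vc[n, term_idx]
            if lock_term[n] > 0:
                lock_term[n] -= 1
            elif prev_term[n] < thr and v >= thr:
                lock_term[n] = lock_steps
                if mode != 2:
                    for k in range(K_cs):
                        z_cs[cs_targets[n, k]] += kick_cs
                    cnt = counters[4]
                    if cnt < term_spk_id.shape[0]:
                        term_spk_id[cnt] = n
                        term_spk_t[cnt] = tnow
                        counters[4] = cnt + 1
                    else:
                        return OVERFLOW
            prev_term[n] = v

            if mode == 2:
                v = Vc[n, n9_idx]
                if lock_n9[n] > 0:
                    lock_n9[n] -= 1
                elif prev_n9[n] < thr and v >= thr:
                    lock_n9[n] = lock_steps
                    last_n9[n] = tnow
                prev_n9[n] = v
                v = Vc[n, n10_idx]
                if lock_n10[n] > 0:
                    lock_n10[n] -= 1
                elif prev_n10[n] < thr and v >= thr:
                    lock_n10[n] = lock_steps
                    if tnow - last_n9[n] < dir_win:
                        # descending (orthodromic) spike: relay to the
                        # synapse-bearing twin collateral after its
                        # transit delay
                        slot = (step + relay_steps) % ring
                        pending[slot, n] = 1
                prev_n10[n] = v

        for i in range(n_stn):
            v = Ystn[i, 0]
            if lock_stn[i] > 0:
                lock_stn[i] -= 1
            elif prev_stn[i] < thr and v >= thr:
                lock_stn[i] = lock_steps
                cnt = counters[2]
                if cnt < stn_spk_id.shape[0]:
                    stn_spk_id[cnt] = i
                    stn_spk_t[cnt] = tnow
                    counters[2] = cnt + 1
                else:
                    return OVERFLOW
                for k in range(K_sg):
                    z_sg[sg_targets[i, k]] += kick_sg
            prev_stn[i] = v
        for i in range(n_gpe):
            v = Ygpe[i, 0]
            if lock_gpe[i] > 0:
                lock_gpe[i] -= 1
            elif prev_gpe[i] < thr and v >= thr:
                lock_gpe[i] = lock_steps
                cnt = counters[3]
                if cnt < gpe_spk_id.shape[0]:
                    gpe_spk_id[cnt] = i
                    gpe_spk_t[cnt] = tnow
                    counters[3] = cnt + 1
                else:
                    return OVERFLOW
                for k in range(gs_ptr[i], gs_ptr[i + 1]):
                    z_gs[gs_tgt[k]] += kick_gs
                for k in range(gg_ptr[i], gg_ptr[i + 1]):
                    z_gg[gg_tgt[k]] += kick_gg
            prev_gpe[i] = v

        # divergence detector
        if step % 50 == 0:
            for n in range(n_cx):
                for c in range(C):
                    if not (-200.0 < Vc[n, c] < 200.0):
                        div_info[0] = 0.0
                        div_info[1] = n * 1000.0 + c
                        div_info[2] = tnow
                        div_info[3] = float(step)
                        return DIVERGED
            for i in range(n_stn):
                if not (-200.0 < Ystn[i, 0] < 200.0):
                    div_info[0] = 2.0
                    div_info[1] = float(i)
                    div_info[2] = tnow
                    return DIVERGED
            for i in range(n_gpe):
                if not (-200.0 < Ygpe[i, 0] < 200.0):
                    div_info[0] = 3.0
                    div_info[1] = float(i)
                    div_info[2] = tnow
                    return DIVERGED
    return OK
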
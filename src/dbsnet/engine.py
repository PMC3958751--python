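"""Time-stepping engine: the :class:`NetworkModel` and its results.

The engine advances the coupled cortico-STN-GPe system with classical
fixed-step RK4 (default dt = 0.01 ms), injects per-neuron Gaussian
membrane noise, and implements the three stimulation propagation modes:

``both``
    DBS-evoked action potentials in the axon collateral propagate in
    both directions (the physiological case).
``orthodromic``
    Propagation from the collateral toward the cortical soma is blocked
    by a one-way junction at the last node: cortical spikes arriving at
    the last node are relayed into the collateral, but collateral
    depolarization does not influence the main axon (its axial
    conductance toward the node is set to zero).
``antidromic``
    Each collateral is represented by a pair of twins: collateral A is
    embedded in the cable, receives the extracellular field and carries
    antidromic spikes into the main axon, but has no synapse onto the
    STN; twin B carries the cortical output to the STN synapses as an
    event copy of descending last-node spikes delayed by the collateral
    transit time, and receives no field.

Runs are deterministic given the model seed and the run noise seed, and
can be split into segments via state snapshots (the pre-DBS state can be
reused across stimulation conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels, neurons
from .cable import build_cable
from .network import build_network
from .params import default_params, merge_params
from .stimulation import DBSSpec, Electrode, extracellular_potential, \
    pulse_onset_times

__all__ = ["PropagationMode", "SimulationProtocol", "SimulationResult",
           "NetworkModel", "EngineState", "step_system",
           "apply_antidromic_only", "apply_orthodromic_only",
           "build_rate_tables", "SimulationError", "DivergenceError"]

MODES = {"both": 0, "orthodromic": 1, "antidromic": 2}

#: Direction-discrimination window (ms) for classifying a last-node spike
#: as descending (orthodromic): the penultimate node must have spiked
#: within this window before the last node.
DIRECTION_WINDOW_MS = 2.0


class SimulationError(RuntimeError):
    pass


class DivergenceError(SimulationError):
    pass


@dataclass(frozen=True)
class PropagationMode:
    """Validated propagation-mode tag (one of both/orthodromic/antidromic)."""
    name: str = "both"

    def __post_init__(self):
        if self.name not in MODES:
            raise ValueError(f"unknown propagation mode {self.name!r}; "
                             f"expected one of {sorted(MODES)}")

    @property
    def code(self) -> int:
        return MODES[self.name]


@dataclass
class SimulationProtocol:
    """Stimulation protocol timing (ms)."""
    duration: float = 5000.0
    dbs_onset: float = 2000.0
    dbs_duration: float = 1000.0
    dt: float = 0.01
    n_repeats: int = 5

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.dbs_onset
                and self.dbs_onset + self.dbs_duration <= self.duration):
            raise ValueError("DBS window must lie within the total duration")


# ----------------------------------------------------------------------
# Rate lookup tables for the cable kernel

_TABLE_VMIN = -150.0
_TABLE_VMAX = 80.0
_TABLE_DV = 0.05


def build_rate_tables(params: dict):
    """Dense (A, B) gating-rate tables with x' = A(V) - B(V) x.

    Built from the exact rate functions of :mod:`dbsnet.neurons` on a
    0.05 mV grid; the kernel interpolates linearly.
    """
    pp_soma = neurons.pack_soma_params(params)
    kin = neurons.pack_axon_kinetics(params)
    kin_coll = neurons.pack_axon_kinetics(params, kind="collateral")
    grid = np.arange(_TABLE_VMIN, _TABLE_VMAX + _TABLE_DV / 2, _TABLE_DV)
    ngrid = len(grid)
    soma_A = np.empty((ngrid, 4))
    soma_B = np.empty((ngrid, 4))
    axon_A = np.empty((ngrid, 5))
    axon_B = np.empty((ngrid, 5))
    coll_A = np.empty((ngrid, 5))
    coll_B = np.empty((ngrid, 5))
    for i, v in enumerate(grid):
        am, bm, ah, bh, an, bn, p_inf, tau_p = neurons.soma_gate_rates(
            v, pp_soma[9], pp_soma[6])
        soma_A[i] = (am, ah, an, p_inf / tau_p)
        soma_B[i] = (am + bm, ah + bh, an + bn, 1.0 / tau_p)
        for kk, A, B in ((kin, axon_A, axon_B), (kin_coll, coll_A, coll_B)):
            am, bm, ah, bh, an, bn, a_inf, tau_a, b_inf, tau_b = \
                neurons.axon_gate_rates(v, kk)
            A[i] = (am, ah, an, a_inf / tau_a, b_inf / tau_b)
            B[i] = (am + bm, ah + bh, an + bn, 1.0 / tau_a, 1.0 / tau_b)
    # interleave A and B per gate (columns 2g, 2g+1) so one grid row
    # per compartment covers all coefficients contiguously
    def interleave(A, B):
        out = np.empty((A.shape[0], 2 * A.shape[1]))
        out[:, 0::2] = A
        out[:, 1::2] = B
        return out

    return (interleave(soma_A, soma_B), interleave(axon_A, axon_B),
            interleave(coll_A, coll_B), _TABLE_VMIN, 1.0 / _TABLE_DV)


# ----------------------------------------------------------------------


@dataclass
class EngineState:
    """Full continuous state of the network (mutated in place by runs)."""
    t: float
    Vc: np.ndarray              # (n_cx, C) cable potentials
    Gc: np.ndarray              # (n_cx, C, 5) cable gating
    v_in: np.ndarray
    u_in: np.ndarray
    Ystn: np.ndarray            # (n_stn, 13)
    Ygpe: np.ndarray            # (n_gpe, 5)
    syn_shared: np.ndarray      # [s_ci, z_ci, s_ic, z_ic]
    s_cs: np.ndarray
    z_cs: np.ndarray
    s_gs: np.ndarray
    z_gs: np.ndarray
    s_sg: np.ndarray
    z_sg: np.ndarray
    s_gg: np.ndarray
    z_gg: np.ndarray
    pending: np.ndarray         # antidromic relay ring buffer

    def copy(self) -> "EngineState":
        return EngineState(**{k: (v.copy() if isinstance(v, np.ndarray)
                                  else v)
                              for k, v in self.__dict__.items()})


@dataclass
class SimulationResult:
    """Spike trains, stimulus times, optional traces and provenance."""
    spikes: dict                 # population -> (ids, times ms)
    pulse_times: np.ndarray
    traces: dict                 # name -> array (time x unit), decimated
    trace_times: np.ndarray
    t0: float
    duration: float
    dt: float
    mode: str
    config: dict = field(default_factory=dict)

    def spike_train(self, population: str, neuron: int) -> np.ndarray:
        ids, times = self.spikes[population]
        return times[ids == neuron]

    def firing_rate(self, population: str) -> float:
        """Mean firing rate (Hz) per neuron over the simulated window."""
        ids, times = self.spikes[population]
        pops = self.config.get("populations", {})
        key = "cortex" if population == "collateral_terminal" else population
        n = pops.get(key, 1)
        return len(times) / n / (self.duration / 1000.0)

    def summary(self) -> str:
        lines = [f"SimulationResult: {self.duration:.0f} ms from "
                 f"t0={self.t0:.0f} ms, mode={self.mode}, dt={self.dt} ms",
                 f"  DBS pulses: {len(self.pulse_times)}"]
        for pop in sorted(self.spikes):
            ids, times = self.spikes[pop]
            lines.append(f"  {pop}: {len(times)} spikes "
                         f"({self.firing_rate(pop):.2f} Hz/neuron)")
        return "\n".join(lines)

    def to_dir(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for pop, (ids, times) in self.spikes.items():
            for i, t in zip(ids, times):
                rows.append((pop, int(i), float(t)))
        pd.DataFrame(rows, columns=["population", "neuron", "time_ms"]
                     ).to_csv(d / "spikes.csv", index=False)
        pd.DataFrame({"pulse_time_ms": self.pulse_times}
                     ).to_csv(d / "pulses.csv", index=False)
        (d / "provenance.json").write_text(json.dumps(self.config, indent=2,
                                                      default=str))


class NetworkModel:
    """Cortico-STN-GPe network with extracellular DBS of the cortical
    axon collaterals.

    Parameters
    ----------
    params : optional parameter tree (see :mod:`dbsnet.params`).
    seed : controls network geometry, connectivity, beta-drive phases
        and initial-state jitter; runs default their noise stream to the
        same seed.
    mode : propagation mode ("both", "orthodromic", "antidromic").
    parkinsonian : apply the dopamine-depleted gain multipliers
        (defaults to the value in the parameter tree).
    """

    def __init__(self, params: dict | None = None, seed: int = 0,
                 mode: str = "both", parkinsonian: bool | None = None):
        self.params = merge_params(default_params(), params or {})
        self.seed = int(seed)
        self.mode = PropagationMode(mode)
        if parkinsonian is not None:
            self.params["parkinsonian"]["enabled"] = bool(parkinsonian)
        self.graph = build_network(self.params, seed=self.seed)
        self.morph = build_cable(self.params)
        self.tables = build_rate_tables(self.params)
        self._setup_static()

    # -- construction helpers -----------------------------------------

    def _setup_static(self):
        p = self.params
        m = self.morph
        g = self.graph
        n_cx = g.populations["cortex"]
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(1,)))

        # per-interneuron latency jitter of the direct stimulus drive
        n_in = g.populations["interneuron"]
        dt = p["engine"]["dt"]
        rng_jit = np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(3,)))
        delay = p["stim"].get("interneuron_drive_delay_ms", 0.0)
        self.in_jitter = np.asarray(
            (delay + rng_jit.uniform(
                0.0, p["stim"]["interneuron_drive_jitter_ms"], n_in))
            / dt, dtype=np.int64)

        # per-neuron beta-drive phases (common rhythm, jittered per neuron)
        bd = p["beta_drive"]
        jitter = rng.normal(0.0, bd["jitter_ms"], n_cx)
        self.beta_frequency = bd["frequency_hz"]
        self.beta_omega = 2.0 * np.pi * self.beta_frequency / 1000.0
        self.beta_phase = self.beta_omega * jitter
        self.beta_amp = np.full(n_cx, bd["amplitude"])

        # extracellular field coefficients per edge (uA per mA of stimulus)
        electrode = Electrode(position=np.asarray(p["stim"]["electrode_xyz"]),
                              sigma=p["stim"]["sigma_s_per_m"])
        ve = np.zeros((n_cx, m.n_comp))
        coords = self._compartment_coords()
        if p["stim"]["full_field"]:
            active = np.arange(m.n_comp)
        else:
            active = m.collateral_idx
        for c in active:
            ve[:, c] = extracellular_potential(coords[:, c, :], 1.0,
                                               electrode)
        e_a = m.edges[:, 0]
        e_b = m.edges[:, 1]
        self.fcoef = m.g_edge[None, :] * (ve[:, e_b] - ve[:, e_a])
        if not p["stim"]["full_field"]:
            # field drive only along edges interior to the collateral:
            # the junction edge would otherwise see the artificial jump
            # between the distant (zero-field) main axon and the
            # collateral; both collateral ends act as sealed boundaries
            # of the activating function.
            self.fcoef[:, m.junction_edge] = 0.0
        self.ve_unit = ve

        # synaptic gains (parkinsonian multipliers applied here)
        syn = p["synapses"]
        pk = p["parkinsonian"]
        mult = {
            "cortex->stn": pk["cortex_stn_gain"] if pk["enabled"] else 1.0,
            "gpe->gpe": pk["gpe_gpe_gain"] if pk["enabled"] else 1.0,
            "stn->gpe": pk["stn_gpe_gain"] if pk["enabled"] else 1.0,
            "gpe->stn": pk["gpe_stn_gain"] if pk["enabled"] else 1.0,
            "cortex->interneuron": 1.0,
            "interneuron->cortex": 1.0,
        }
        self.gains = {k: syn[k]["gain"] * mult[k] for k in syn}
        self.taus = {k: syn[k]["tau"] for k in syn}
        self.erevs = {k: syn[k]["e_rev"] for k in syn}

        # connectivity in kernel form
        n_stn = g.populations["stn"]
        n_gpe = g.populations["gpe"]
        pre, post = g.edges["cortex->stn"]
        k = len(post) // n_cx
        self.cs_targets = np.asarray(post, dtype=np.int64).reshape(n_cx, k)
        pre, post = g.edges["stn->gpe"]
        k = len(post) // n_stn
        self.sg_targets = np.asarray(post, dtype=np.int64).reshape(n_stn, k)
        self.gs_ptr, self.gs_tgt = _csr(g.edges["gpe->stn"], n_gpe)
        self.gg_ptr, self.gg_tgt = _csr(g.edges["gpe->gpe"], n_gpe)

        self._axial_cache: dict = {}
        self.pp_soma = neurons.pack_soma_params(p)
        self.pp_stn = neurons.pack_stn_params(p)
        self.pp_gpe = neurons.pack_gpe_params(p)
        self.axon_kin = neurons.pack_axon_kinetics(p)
        self.axon_kin_coll = neurons.pack_axon_kinetics(p, kind="collateral")
        self.relay_steps = max(1, int(round(
            p["engine"]["collateral_relay_delay"] / p["engine"]["dt"])))

    def _axial_matrices(self, mode_code: int):
        """Backward-Euler propagator of the axial + extracellular
        coupling: V <- Minv (V + dt C^-1 f I_stim).

        The axial operator is linear, so the stiff coupling between the
        small nodes and their neighbours is advanced implicitly (exact
        damping of sub-step equilibration) while the nonlinear membrane
        currents use explicit RK4.  In orthodromic-only mode the
        junction row is asymmetric: the last node is decoupled from the
        collateral while still driving it.
        """
        key = mode_code if mode_code == 1 else 0
        if key in self._axial_cache:
            return self._axial_cache[key]
        m = self.morph
        dt = self.params["engine"]["dt"]
        C = m.n_comp
        n_cx = self.graph.populations["cortex"]
        A = np.zeros((C, C))
        f = np.zeros((n_cx, C))
        for e, (a, b) in enumerate(m.edges):
            g = m.g_edge[e]
            blocked = (key == 1 and e == m.junction_edge)
            if not blocked:
                A[a, a] -= g
                A[a, b] += g
                f[:, a] += self.fcoef[:, e]
            A[b, b] -= g
            A[b, a] += g
            f[:, b] -= self.fcoef[:, e]
        cinv = 1.0 / (m.cm * m.areas)      # mV/ms per uA
        minv = np.linalg.inv(np.eye(C) - dt * (cinv[None, :].T * A))
        gstim = (dt * f * cinv[None, :]) @ minv.T
        out = (np.ascontiguousarray(minv), np.ascontiguousarray(gstim))
        self._axial_cache[key] = out
        return out

    def _compartment_coords(self) -> np.ndarray:
        """3-D coordinates (um) of every compartment of every neuron.

        Collaterals run parallel to z through the cloud; the main axon
        extends radially away from the electrode in the x-y plane from
        the branch point (it only matters in full-field mode).
        """
        m = self.morph
        g = self.graph
        n_cx = g.populations["cortex"]
        coords = np.zeros((n_cx, m.n_comp, 3))
        xy = g.collateral_xy
        z0 = g.collateral_z0
        half_l = self.params["geometry"]["collateral_l"] / 2.0
        for j, c in enumerate(m.collateral_idx):
            coords[:, c, 0] = xy[:, 0]
            coords[:, c, 1] = xy[:, 1]
            coords[:, c, 2] = z0 + m.arc_z[j]
        # main axon: walk from the last node radially outward
        r = np.linalg.norm(xy, axis=1)
        u = xy / r[:, None]
        order = [int(m.node_idx[-1])]
        c = order[0]
        while c > 0:
            c -= 1
            order.append(c)
        dist = 0.0
        prev = order[0]
        coords[:, prev, 0] = xy[:, 0]
        coords[:, prev, 1] = xy[:, 1]
        coords[:, prev, 2] = z0 - half_l
        for c in order[1:]:
            dist += (m.lengths[prev] + m.lengths[c]) / 2.0
            coords[:, c, 0] = xy[:, 0] + u[:, 0] * dist
            coords[:, c, 1] = xy[:, 1] + u[:, 1] * dist
            coords[:, c, 2] = z0 - half_l
            prev = c
        # internodes hang off the chain in index order; the loop above
        # covers them because indices soma..last-internode are contiguous
        return coords

    # -- state ---------------------------------------------------------

    def initial_state(self, v_jitter: float = 3.0) -> EngineState:
        """Resting initial state with small per-neuron voltage jitter."""
        g = self.graph
        m = self.morph
        n_cx = g.populations["cortex"]
        n_in = g.populations["interneuron"]
        n_stn = g.populations["stn"]
        n_gpe = g.populations["gpe"]
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(2,)))
        Vc = np.empty((n_cx, m.n_comp))
        Gc = np.empty((n_cx, m.n_comp, 5))
        soma0 = neurons.soma_init(self.pp_soma)
        axon0 = neurons.axon_init(self.axon_kin)
        Vc[:, 0] = soma0[0]
        Gc[:, 0, :4] = soma0[1:]
        Gc[:, 0, 4] = 0.0
        for c in range(1, m.n_comp):
            Vc[:, c] = axon0[0]
            Gc[:, c, :] = axon0[1:]
        inp = self.params["interneuron"]
        v_in = np.full(n_in, inp["c"]) + rng.uniform(-v_jitter, v_jitter, n_in)
        u_in = inp["b"] * v_in
        Ystn = np.empty((n_stn, 13))
        Ygpe = np.empty((n_gpe, 5))
        for i in range(n_stn):
            Ystn[i] = neurons.stn_init(self.pp_stn,
                                       v0=-58.0 + rng.uniform(-v_jitter,
                                                              v_jitter))
        for i in range(n_gpe):
            Ygpe[i] = neurons.gpe_init(self.pp_gpe,
                                       v0=-62.0 + rng.uniform(-v_jitter,
                                                              v_jitter))
        return EngineState(
            t=0.0, Vc=Vc, Gc=Gc, v_in=v_in, u_in=u_in, Ystn=Ystn, Ygpe=Ygpe,
            syn_shared=np.zeros(4),
            s_cs=np.zeros(n_stn), z_cs=np.zeros(n_stn),
            s_gs=np.zeros(n_stn), z_gs=np.zeros(n_stn),
            s_sg=np.zeros(n_gpe), z_sg=np.zeros(n_gpe),
            s_gg=np.zeros(n_gpe), z_gg=np.zeros(n_gpe),
            pending=np.zeros((self.relay_steps + 1, n_cx), dtype=np.uint8))

    # -- simulation -----------------------------------------------------

    def simulate(self, duration: float, dbs: DBSSpec | None = None,
                 state: EngineState | None = None,
                 noise_seed: int | None = None,
                 record: tuple = (), trace_decimation: int = 10,
                 cable_record_neuron: int = 0,
                 beta: bool = True) -> tuple[SimulationResult, EngineState]:
        """Advance the network by ``duration`` ms.

        Parameters
        ----------
        dbs : optional stimulus; pulses outside the segment are ignored.
        state : continue from this state (default: fresh initial state).
        record : any of {"cortex_soma", "interneuron", "stn", "gpe",
            "cable"} to store decimated membrane traces.
        beta : apply the parkinsonian cortical beta drive.

        Returns the (result, final_state) pair; the passed-in state is
        not mutated.
        """
        p = self.params
        dt = p["engine"]["dt"]
        n_steps = int(round(duration / dt))
        if state is None:
            state = self.initial_state()
        st = state.copy()
        t0 = st.t
        g = self.graph
        m = self.morph
        n_cx = g.populations["cortex"]
        n_in = g.populations["interneuron"]
        n_stn = g.populations["stn"]
        n_gpe = g.populations["gpe"]

        # stimulus alignment to the step grid
        stim_active = np.zeros(n_steps, dtype=np.uint8)
        in_drive_active = np.zeros(n_steps, dtype=np.uint8)
        pulse_times = np.empty(0)
        i_amp = 0.0
        if dbs is not None:
            i_amp = dbs.i_d
            onsets = pulse_onset_times(dbs, t0 + duration)
            onsets = onsets[onsets >= t0]
            wsteps = max(1, int(round(dbs.delta_d / dt)))
            dsteps = max(1, int(round(p["stim"]["interneuron_drive_ms"] / dt)))
            snapped = []
            for tp in onsets:
                s0 = int(round((tp - t0) / dt))
                if s0 >= n_steps:
                    continue
                snapped.append(t0 + s0 * dt)
                stim_active[s0:s0 + wsteps] = 1
                in_drive_active[s0:s0 + dsteps] = 1
            pulse_times = np.array(snapped)

        seed = (self.seed if noise_seed is None else int(noise_seed)) % (2**31)

        rec_dec = int(trace_decimation)
        n_rec = -(-n_steps // rec_dec)

        def _rec(name, ncols):
            if name in record:
                return np.zeros((n_rec, ncols), dtype=np.float64)
            return np.zeros((0, ncols), dtype=np.float64)

        rec_cx = _rec("cortex_soma", n_cx)
        rec_in = _rec("interneuron", n_in)
        rec_stn = _rec("stn", n_stn)
        rec_gpe = _rec("gpe", n_gpe)
        rec_cable = _rec("cable", m.n_comp)

        # generous per-population spike caps: 0.5 spikes/ms/neuron
        def _spk(n):
            c = int(n * duration * 0.5) + 4096
            return np.zeros(c, dtype=np.int32), np.zeros(c, dtype=np.float64)

        cx_spk_id, cx_spk_t = _spk(n_cx)
        in_spk_id, in_spk_t = _spk(n_in)
        stn_spk_id, stn_spk_t = _spk(n_stn)
        gpe_spk_id, gpe_spk_t = _spk(n_gpe)
        term_spk_id, term_spk_t = _spk(n_cx)
        counters = np.zeros(8, dtype=np.int64)
        div_info = np.zeros(4)

        beta_amp = self.beta_amp if beta else np.zeros(n_cx)
        eng = p["engine"]
        status = _kernels.run_network(
            n_steps, dt, t0, seed,
            stim_active, in_drive_active, i_amp,
            p["stim"]["interneuron_drive_amp"], self.in_jitter,
            self.mode.code,
            st.Vc, st.Gc, m.kinds, m.areas, m.cm, m.g_na, m.g_k, m.g_kd,
            m.g_leak, m.e_leak, *self._axial_matrices(self.mode.code),
            *self.tables,
            p["axon"]["e_na"], p["axon"]["e_k"],
            m.terminal_idx, int(m.node_idx[-1]), int(m.node_idx[-2]),
            beta_amp, self.beta_phase, self.beta_omega,
            st.v_in, st.u_in,
            p["interneuron"]["a"], p["interneuron"]["b"],
            p["interneuron"]["c"], p["interneuron"]["d"],
            p["interneuron"]["v_peak"],
            st.Ystn, self.pp_stn, st.Ygpe, self.pp_gpe,
            st.syn_shared,
            self.taus["cortex->interneuron"], self.taus["interneuron->cortex"],
            self.gains["cortex->interneuron"],
            self.gains["interneuron->cortex"],
            self.erevs["interneuron->cortex"],
            st.s_cs, st.z_cs, st.s_gs, st.z_gs, st.s_sg, st.z_sg,
            st.s_gg, st.z_gg,
            self.taus["cortex->stn"], self.taus["gpe->stn"],
            self.taus["stn->gpe"], self.taus["gpe->gpe"],
            self.gains["cortex->stn"], self.gains["gpe->stn"],
            self.gains["stn->gpe"], self.gains["gpe->gpe"],
            self.erevs["gpe->stn"], self.erevs["gpe->gpe"],
            self.cs_targets, self.gs_ptr, self.gs_tgt, self.sg_targets,
            self.gg_ptr, self.gg_tgt,
            self.relay_steps, st.pending, DIRECTION_WINDOW_MS,
            p["noise"]["sigma"], eng["spike_threshold"],
            int(round(eng["spike_lockout"] / dt)),
            rec_dec, rec_cx, rec_in, rec_stn, rec_gpe, rec_cable,
            int(cable_record_neuron),
            cx_spk_id, cx_spk_t, in_spk_id, in_spk_t,
            stn_spk_id, stn_spk_t, gpe_spk_id, gpe_spk_t,
            term_spk_id, term_spk_t, counters, div_info)

        if status == _kernels.DIVERGED:
            pop = {0: "cortex", 2: "stn", 3: "gpe"}[int(div_info[0])]
            which = int(div_info[1])
            detail = (f"neuron {which // 1000} compartment {which % 1000}"
                      if pop == "cortex" else f"neuron {which}")
            raise DivergenceError(
                f"|Vm| exceeded {eng['divergence_mv']} mV in {pop} "
                f"{detail} at t = {div_info[2]:.2f} ms")
        if status == _kernels.OVERFLOW:
            raise SimulationError("spike buffer overflow (firing rate far "
                                  "above the expected range)")

        # roll the relay ring so a continuation starts at slot 0
        shift = n_steps % (self.relay_steps + 1)
        if shift:
            st.pending = np.roll(st.pending, -shift, axis=0)
        st.t = t0 + n_steps * dt

        spikes = {
            "cortex": (cx_spk_id[:counters[0]].copy(),
                       cx_spk_t[:counters[0]].copy()),
            "interneuron": (in_spk_id[:counters[1]].copy(),
                            in_spk_t[:counters[1]].copy()),
            "stn": (stn_spk_id[:counters[2]].copy(),
                    stn_spk_t[:counters[2]].copy()),
            "gpe": (gpe_spk_id[:counters[3]].copy(),
                    gpe_spk_t[:counters[3]].copy()),
            "collateral_terminal": (term_spk_id[:counters[4]].copy(),
                                    term_spk_t[:counters[4]].copy()),
        }
        traces = {}
        for name, arr in (("cortex_soma", rec_cx), ("interneuron", rec_in),
                          ("stn", rec_stn), ("gpe", rec_gpe),
                          ("cable", rec_cable)):
            if arr.shape[0] > 0:
                traces[name] = arr
        trace_times = t0 + np.arange(n_rec) * dt * rec_dec
        config = {
            "seed": self.seed, "noise_seed": seed, "mode": self.mode.name,
            "dt": dt, "t0": t0, "duration": duration,
            "parkinsonian": p["parkinsonian"]["enabled"],
            "beta": bool(beta),
            "dbs": None if dbs is None else {
                "i_d_ma": dbs.i_d, "rho_d_ms": dbs.rho_d,
                "delta_d_ms": dbs.delta_d, "frequency_hz": dbs.frequency_hz},
            "populations": dict(g.populations),
            "params_version": p.get("version"),
        }
        result = SimulationResult(
            spikes=spikes, pulse_times=pulse_times, traces=traces,
            trace_times=trace_times, t0=t0, duration=duration, dt=dt,
            mode=self.mode.name, config=config)
        return result, st


def _csr(edge_pair, n_pre):
    pre = np.asarray(edge_pair[0], dtype=np.int64)
    post = np.asarray(edge_pair[1], dtype=np.int64)
    order = np.argsort(pre, kind="stable")
    pre_s = pre[order]
    tgt = post[order]
    ptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(ptr, pre_s + 1, 1)
    return np.cumsum(ptr), tgt


def step_system(model: NetworkModel, state: EngineState, dt: float | None
                = None, dbs: DBSSpec | None = None, **kw
                ) -> tuple[SimulationResult, EngineState]:
    """Advance the whole coupled system by a single RK4 step."""
    step = model.params["engine"]["dt"] if dt is None else dt
    return model.simulate(step, dbs=dbs, state=state, **kw)


def apply_antidromic_only(model: NetworkModel) -> NetworkModel:
    """Configure the paired-collateral antidromic-only arrangement."""
    model.mode = PropagationMode("antidromic")
    return model


def apply_orthodromic_only(model: NetworkModel) -> NetworkModel:
    """Configure the junction-blocked orthodromic-only arrangement."""
    model.mode = PropagationMode("orthodromic")
    return model
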
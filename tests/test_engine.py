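"""Engine-level tests: determinism, propagation modes, collision
annihilation and integrator consistency."""

import numpy as np
import pytest

from dbsnet import neurons, reference
from dbsnet.cable import build_cable
from dbsnet.engine import (NetworkModel, PropagationMode,
                           SimulationProtocol, apply_antidromic_only,
                           apply_orthodromic_only)
from dbsnet.params import default_params, merge_params
from dbsnet.stimulation import frequency_to_spec

SMALL = {"network": {"n_cortical": 4, "n_interneuron": 4, "n_stn": 10,
                     "n_gpe": 4}}


def small_model(mode="both", seed=3, extra=None):
    p = merge_params(default_params(), SMALL)
    if extra:
        p = merge_params(p, extra)
    return NetworkModel(p, seed=seed, mode=mode)


class TestProtocolAndModes:
    def test_mode_validation(self):
        with pytest.raises(ValueError):
            PropagationMode("sideways")
        assert PropagationMode("antidromic").code == 2

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            SimulationProtocol(duration=1000.0, dbs_onset=500.0,
                               dbs_duration=600.0)
        with pytest.raises(ValueError):
            SimulationProtocol(dt=0.0)

    def test_apply_mode_helpers(self):
        m = small_model()
        apply_antidromic_only(m)
        assert m.mode.name == "antidromic"
        apply_orthodromic_only(m)
        assert m.mode.name == "orthodromic"


class TestDeterminism:
    def test_identical_seeds_identical_spike_trains(self):
        dbs = frequency_to_spec(130.0, 2.1, 60.0)
        runs = []
        for _ in range(2):
            m = small_model()
            res, _ = m.simulate(300.0, dbs=dbs)
            runs.append(res)
        for pop in runs[0].spikes:
            a_ids, a_t = runs[0].spikes[pop]
            b_ids, b_t = runs[1].spikes[pop]
            assert np.array_equal(a_ids, b_ids)
            assert np.array_equal(a_t, b_t)

    def test_different_noise_seed_differs(self):
        m = small_model()
        res_a, _ = m.simulate(400.0, noise_seed=1)
        res_b, _ = m.simulate(400.0, noise_seed=2)
        assert not np.array_equal(res_a.spikes["cortex"][1],
                                  res_b.spikes["cortex"][1])

    def test_dbs_off_modes_agree_for_cortex(self):
        # without stimulation the antidromic twin arrangement and the
        # physiological arrangement produce identical cortical dynamics
        res = {}
        for mode in ("both", "antidromic"):
            m = small_model(mode)
            r, _ = m.simulate(400.0)
            res[mode] = r
        assert np.array_equal(res["both"].spikes["cortex"][1],
                              res["antidromic"].spikes["cortex"][1])
        assert np.array_equal(res["both"].spikes["interneuron"][1],
                              res["antidromic"].spikes["interneuron"][1])

    def test_orthodromic_valve_without_dbs_preserves_cortical_firing(self):
        # the one-way junction only blocks the collateral-to-axon
        # direction; cortical somatic firing stays close to the
        # physiological arrangement (spike-for-spike within ~1 ms)
        r_both, _ = small_model("both").simulate(400.0)
        r_orth, _ = small_model("orthodromic").simulate(400.0)
        a = r_both.spikes["cortex"][1]
        b = r_orth.spikes["cortex"][1]
        assert abs(len(a) - len(b)) <= max(2, 0.1 * len(a))
        n = min(len(a), len(b))
        if n:
            assert np.max(np.abs(np.sort(a)[:n] - np.sort(b)[:n])) < 2.0


class TestQuiescence:
    def test_no_input_network_stays_at_rest(self):
        extra = {"beta_drive": {"amplitude": 0.0}, "noise": {"sigma": 0.0},
                 "synapses": {k: {"gain": 0.0} for k in (
                     "cortex->stn", "gpe->stn", "stn->gpe", "gpe->gpe",
                     "cortex->interneuron", "interneuron->cortex")}}
        m = small_model(extra=extra)
        res, st = m.simulate(100.0)
        assert len(res.spikes["cortex"][1]) == 0
        v0 = st.Vc.copy()
        res2, st2 = m.simulate(10.0, state=st)
        assert np.max(np.abs(st2.Vc - v0)) < 0.5

    def test_membrane_potentials_bounded(self):
        m = small_model()
        res, st = m.simulate(500.0, record=("cortex_soma", "stn", "gpe"))
        for name in ("cortex_soma", "stn", "gpe"):
            tr = res.traces[name]
            assert tr.min() > -120.0 and tr.max() < 60.0

    def test_gating_stays_in_unit_interval(self):
        m = small_model()
        _, st = m.simulate(500.0)
        assert st.Gc.min() >= 0.0 and st.Gc.max() <= 1.0
        assert st.Ystn[:, 1:12].min() >= 0.0
        assert st.Ystn[:, 1:12].max() <= 1.0


class TestPropagation:
    def test_somatic_spike_reaches_terminal_with_delay(self):
        # beta-driven somatic spikes appear at the collateral terminal
        # after a positive propagation delay
        m = small_model()
        res, _ = m.simulate(400.0)
        ids, ts = res.spikes["cortex"]
        tids, tts = res.spikes["collateral_terminal"]
        assert len(ts) > 0 and len(tts) > 0
        delays = []
        for n in range(4):
            own = np.sort(ts[ids == n])
            term = np.sort(tts[tids == n])
            for t in own:
                nxt = term[(term > t) & (term < t + 8.0)]
                if len(nxt):
                    delays.append(nxt[0] - t)
        assert len(delays) > 0
        assert 0.1 < np.mean(delays) < 6.0

    def test_engine_matches_reference_cable_spike_times(self):
        # production kernel (tables + implicit axial step, dt = 0.01)
        # vs the pure fine-step RK4 reference on one beta-driven neuron
        extra = {"beta_drive": {"amplitude": 4.5, "jitter_ms": 0.0},
                 "noise": {"sigma": 0.0},
                 "synapses": {"interneuron->cortex": {"gain": 0.0},
                              "cortex->interneuron": {"gain": 0.0}}}
        m = small_model(extra=extra)
        res, _ = m.simulate(300.0)
        kernel_spikes = np.sort(res.spike_train("cortex", 0))

        morph = m.morph
        C = morph.n_comp
        dt = 0.00025
        n = int(300.0 / dt)
        V = np.empty(C)
        G = np.empty((C, 5))
        s0 = neurons.soma_init(m.pp_soma)
        a0 = neurons.axon_init(m.axon_kin)
        V[0] = s0[0]
        G[0, :4] = s0[1:]
        G[0, 4] = 0.0
        for c in range(1, C):
            V[c] = a0[0]
            G[c, :] = a0[1:]
        t = np.arange(n) * dt
        i_inj = np.zeros((n, C))
        i_inj[:, 0] = 4.5 * np.maximum(
            0.0, np.sin(m.beta_omega * t + m.beta_phase[0]))
        tr = reference.integrate_cable(
            V, G, i_inj, np.zeros(n), dt, morph.kinds, morph.areas,
            morph.cm, morph.g_na, morph.g_k, morph.g_kd, morph.g_leak,
            morph.e_leak, morph.edges, morph.g_edge,
            np.zeros(len(morph.g_edge)), False, morph.junction_edge,
            m.pp_soma, m.axon_kin, m.axon_kin_coll, 50.0, -90.0, 20)
        ref_spikes = reference.upward_crossings(tr[:, 0], -10.0, dt * 20)
        assert len(kernel_spikes) == len(ref_spikes)
        assert np.max(np.abs(kernel_spikes - ref_spikes)) < 1.0


class TestCollisionAnnihilation:
    """Counter-propagating action potentials annihilate on collision;
    emergent from the membrane dynamics, checked on the reference
    cable."""

    @staticmethod
    def _run(inject_soma, inject_terminal, offset_ms=0.0, dur=25.0):
        p = default_params()
        m = build_cable(p)
        pp_soma = neurons.pack_soma_params(p)
        kin = neurons.pack_axon_kinetics(p)
        kin_coll = neurons.pack_axon_kinetics(p, kind="collateral")
        C = m.n_comp
        dt = 0.00025
        n = int(dur / dt)
        V = np.empty(C)
        G = np.empty((C, 5))
        s0 = neurons.soma_init(pp_soma)
        a0 = neurons.axon_init(kin)
        V[0] = s0[0]
        G[0, :4] = s0[1:]
        G[0, 4] = 0.0
        for c in range(1, C):
            V[c] = a0[0]
            G[c, :] = a0[1:]
        i_inj = np.zeros((n, C))
        if inject_soma:
            i_inj[:int(2.0 / dt), 0] = 20.0
        if inject_terminal:
            s = int(offset_ms / dt)
            i_inj[s:s + int(1.0 / dt), m.terminal_idx] = 800.0
        tr = reference.integrate_cable(
            V, G, i_inj, np.zeros(n), dt, m.kinds, m.areas, m.cm, m.g_na,
            m.g_k, m.g_kd, m.g_leak, m.e_leak, m.edges, m.g_edge,
            np.zeros(len(m.g_edge)), False, m.junction_edge, pp_soma, kin,
            kin_coll, 50.0, -90.0, 20)
        soma_spk = reference.upward_crossings(tr[:, 0], -10.0, dt * 20)
        term_spk = reference.upward_crossings(tr[:, m.terminal_idx], -10.0,
                                              dt * 20)
        mid_spk = reference.upward_crossings(tr[:, m.node_idx[4]], -10.0,
                                             dt * 20)
        return soma_spk, term_spk, mid_spk

    def test_single_orthodromic_spike_full_transit(self):
        soma, term, mid = self._run(True, False)
        assert len(soma) == 1 and len(mid) == 1 and len(term) == 1

    def test_single_antidromic_spike_full_transit(self):
        soma, term, mid = self._run(False, True)
        assert len(term) == 1 and len(mid) == 1 and len(soma) == 1

    def test_opposing_spikes_annihilate(self):
        # soma spike launched at t=0, terminal spike at the same time:
        # they meet in the main axon and cancel; each far end sees only
        # its locally initiated spike and no arriving one
        soma, term, mid = self._run(True, True, offset_ms=0.5)
        assert len(soma) == 1    # no antidromic arrival on top
        assert len(term) == 1    # no orthodromic arrival
        assert len(mid) <= 1

    def test_large_offset_both_transit(self):
        soma, term, mid = self._run(True, True, offset_ms=14.0)
        assert len(mid) == 2
        assert len(term) == 2 or len(soma) == 2


class TestConvergence:
    def test_halving_dt_changes_rates_little(self):
        extra = {"engine": {"dt": 0.01}}
        m1 = small_model(extra=extra)
        r1, _ = m1.simulate(500.0)
        m2 = small_model(extra={"engine": {"dt": 0.005}})
        r2, _ = m2.simulate(500.0)
        n1 = len(r1.spikes["cortex"][1])
        n2 = len(r2.spikes["cortex"][1])
        assert n1 > 0
        assert abs(n1 - n2) <= max(1, 0.05 * n1)
        g1 = len(r1.spikes["gpe"][1])
        g2 = len(r2.spikes["gpe"][1])
        assert abs(g1 - g2) <= max(2, 0.05 * g1)
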
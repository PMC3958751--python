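"""Single-cell model tests: equilibria, firing behavior, and agreement
with fine-step reference integration."""

import numpy as np
import pytest

from dbsnet import neurons, reference
from dbsnet.neurons import (AxonCompartmentState, ChannelDensityTable,
                            CorticalSomaState, GPeState, InterneuronState,
                            STNState, axon_derivatives, gpe_derivatives,
                            interneuron_step, soma_derivatives,
                            stn_derivatives)
from dbsnet.params import default_params

DT = 0.01


@pytest.fixture(scope="module")
def pp_soma():
    return neurons.pack_soma_params(default_params())


@pytest.fixture(scope="module")
def pp_stn():
    return neurons.pack_stn_params(default_params())


@pytest.fixture(scope="module")
def pp_gpe():
    return neurons.pack_gpe_params(default_params())


def rate_from_trace(v, dt):
    return len(reference.upward_crossings(v, -10.0, dt)) / \
        ((len(v) - 1) * dt / 1000.0)


class TestCorticalSoma:
    def test_rest_is_a_fixed_point(self, pp_soma):
        y0 = neurons.soma_init(pp_soma)
        state = CorticalSomaState(vm=y0[0], m=y0[1], h=y0[2], n=y0[3],
                                  p=y0[4])
        dy = soma_derivatives(state)
        assert np.allclose(dy, 0.0, atol=1e-6)

    def test_resting_potential_stable_over_500_ms(self, pp_soma):
        y0 = neurons.soma_init(pp_soma)
        n = int(500 / DT)
        v = reference.integrate_soma(y0, np.zeros(n), DT, n, pp_soma)
        assert abs(v[-1] - v[0]) < 0.5

    def test_spike_frequency_adaptation(self, pp_soma):
        # sustained suprathreshold injection: later ISIs longer than
        # early ones (slow K+ adaptation current)
        y0 = neurons.soma_init(pp_soma)
        n = int(1000 / DT)
        v = reference.integrate_soma(y0, np.full(n, 1.5), DT, n, pp_soma)
        spikes = reference.upward_crossings(v, -10.0, DT)
        isis = np.diff(spikes)
        assert len(isis) >= 3
        assert isis[-1] > 1.2 * isis[0]

    def test_fi_curve_monotone_and_matches_fine_step(self, pp_soma):
        y0 = neurons.soma_init(pp_soma)
        rates, rates_fine = [], []
        for amp in (1.0, 2.0, 4.0):
            n = int(800 / DT)
            v = reference.integrate_soma(y0, np.full(n, amp), DT, n, pp_soma)
            rates.append(rate_from_trace(v, DT))
            nf = int(800 / (DT / 10))
            vf = reference.integrate_soma(y0, np.full(nf, amp), DT / 10, nf,
                                          pp_soma)
            rates_fine.append(rate_from_trace(vf, DT / 10))
        assert rates[0] < rates[1] < rates[2]
        assert np.allclose(rates, rates_fine, rtol=0.05)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError, match="vm"):
            soma_derivatives(CorticalSomaState(vm=float("nan")))
        with pytest.raises(ValueError):
            soma_derivatives(CorticalSomaState(), i_inj=float("inf"))


class TestAxonCompartment:
    def test_internode_kd_contribution_exactly_zero(self):
        table = ChannelDensityTable.from_params(default_params())
        st_a = AxonCompartmentState(vm=-30.0, m=0.4, h=0.5, n=0.3, a=0.7,
                                    b=0.6, kind="internode")
        dy = axon_derivatives(st_a, table)
        # recompute with the Kd gates forced shut: identical dVm/dt
        st_b = AxonCompartmentState(vm=-30.0, m=0.4, h=0.5, n=0.3, a=0.0,
                                    b=0.0, kind="internode")
        assert dy[0] == pytest.approx(axon_derivatives(st_b, table)[0])

    def test_all_off_gating_at_leak_reversal(self):
        table = ChannelDensityTable.from_params(default_params())
        p = default_params()
        st = AxonCompartmentState(vm=p["axon"]["e_leak"], m=0.0, h=1.0,
                                  n=0.0, a=0.0, b=1.0, kind="node")
        drive = 3.7
        dy = axon_derivatives(st, table, drive=drive)
        assert dy[0] == pytest.approx(drive / p["axon"]["cm"])

    def test_unknown_kind_rejected(self):
        table = ChannelDensityTable.from_params(default_params())
        with pytest.raises(ValueError):
            axon_derivatives(AxonCompartmentState(kind="dendrite"), table)

    def test_node_spike_peak_matches_fine_step(self):
        # brief depolarization of an isolated node -> regenerative spike
        # whose peak agrees with a 10x finer integration
        p = default_params()
        kin = neurons.pack_axon_kinetics(p)
        table = ChannelDensityTable.from_params(p)
        g_na, g_k, g_kd, g_leak = table.row("node")

        def run(dt):
            y = neurons.axon_init(kin)
            peak = -100.0
            n = int(10 / dt)
            for s in range(n):
                drive = 50.0 if s * dt < 0.5 else 0.0
                k1 = neurons.axon_rhs(y, g_na, g_k, g_kd, g_leak, 1.0,
                                      drive, kin)
                k2 = neurons.axon_rhs(y + 0.5 * dt * k1, g_na, g_k, g_kd,
                                      g_leak, 1.0, drive, kin)
                k3 = neurons.axon_rhs(y + 0.5 * dt * k2, g_na, g_k, g_kd,
                                      g_leak, 1.0, drive, kin)
                k4 = neurons.axon_rhs(y + dt * k3, g_na, g_k, g_kd, g_leak,
                                      1.0, drive, kin)
                y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                peak = max(peak, y[0])
            return peak

        assert run(DT) > 0.0
        assert abs(run(DT) - run(DT / 10)) < 1.0


class TestInterneuron:
    def test_reset_rule_is_exact(self):
        st = InterneuronState(vm=31.0, u=-10.0)
        out, spiked = interneuron_step(st, 100.0, 0.01)
        assert spiked
        assert out.vm == st.c
        assert out.u == pytest.approx(-10.0 + st.d, abs=0.05)

    def test_no_step_leaves_vm_above_threshold(self):
        st = InterneuronState()
        for _ in range(20000):
            st, _ = interneuron_step(st, 20.0, 0.01)
            assert st.vm < st.v_peak

    def test_subthreshold_fixed_point_stable(self):
        # v* solving 0.04 v^2 + 5 v + 140 - b v = 0 (lower root), u = b v
        b = 0.2
        v_star = (-(5 - b) - np.sqrt((5 - b) ** 2 - 4 * 0.04 * 140)) \
            / (2 * 0.04)
        st = InterneuronState(vm=v_star, u=b * v_star)
        out, spiked = interneuron_step(st, 0.0, 0.01)
        assert not spiked
        assert out.vm == pytest.approx(v_star, abs=1e-9)

    def test_rate_curve_matches_fine_step(self):
        p = default_params()["interneuron"]
        for amp in (8.0, 14.0, 20.0):
            n = int(1000 / DT)
            _, n_coarse = reference.integrate_izh(
                -65.0, -13.0, np.full(n, amp), DT, n, p["a"], p["b"],
                p["c"], p["d"], p["v_peak"])
            nf = int(1000 / (DT / 10))
            _, n_fine = reference.integrate_izh(
                -65.0, -13.0, np.full(nf, amp), DT / 10, nf, p["a"],
                p["b"], p["c"], p["d"], p["v_peak"])
            assert n_coarse == pytest.approx(n_fine, rel=0.05, abs=1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            interneuron_step(InterneuronState(), 1.0, 0.0)
        with pytest.raises(ValueError):
            interneuron_step(InterneuronState(), float("nan"), 0.01)


class TestSTN:
    def test_autonomous_rate_matches_fine_step(self, pp_stn):
        y0 = neurons.stn_init(pp_stn)
        n = int(2000 / DT)
        tr = reference.integrate_stn(y0, np.zeros(n), DT, n, pp_stn)
        rate = rate_from_trace(tr[:, 0], DT)
        assert rate > 0
        nf = int(2000 / (DT / 10))
        trf = reference.integrate_stn(y0, np.zeros(nf), DT / 10, nf, pp_stn)
        rate_f = rate_from_trace(trf[:, 0], DT / 10)
        assert rate == pytest.approx(rate_f, rel=0.05)

    def test_rebound_burst_after_hyperpolarization(self, pp_stn):
        y0 = neurons.stn_init(pp_stn)
        n1, n2 = int(500 / DT), int(200 / DT)
        i = np.concatenate([np.full(n1, 8.0), np.zeros(n2)])
        tr = reference.integrate_stn(y0, i, DT, n1 + n2, pp_stn)
        release = tr[n1:, 0]
        spikes = reference.upward_crossings(release, -10.0, DT)
        assert np.sum(spikes < 100.0) > 1

    def test_gating_derivatives_zero_at_steady_state(self, pp_stn):
        v0 = -58.0
        y = neurons.stn_init(pp_stn, v0=v0)
        y[12] = 0.05
        dy = neurons.stn_rhs(y, 0.0, pp_stn)
        # with Ca clamped at the value used to build the steady state,
        # all gating derivatives vanish
        assert np.allclose(dy[1:12], 0.0, atol=1e-10)

    def test_gating_in_unit_interval_and_ca_positive(self, pp_stn):
        y0 = neurons.stn_init(pp_stn)
        rng = np.random.default_rng(5)
        i = rng.uniform(-10, 10, int(2000 / DT))
        tr = reference.integrate_stn(y0, i, DT, len(i), pp_stn)
        gates = tr[:, 1:12]
        assert gates.min() >= -1e-9 and gates.max() <= 1 + 1e-9
        assert tr[:, 12].min() >= -1e-12

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            stn_derivatives(STNState(ca=-0.1))


class TestGPe:
    def test_autonomous_tonic_rate_matches_fine_step(self, pp_gpe):
        y0 = neurons.gpe_init(pp_gpe)
        n = int(2000 / DT)
        tr = reference.integrate_gpe(y0, np.zeros(n), DT, n, pp_gpe)
        rate = rate_from_trace(tr[:, 0], DT)
        assert rate > 10.0
        nf = int(2000 / (DT / 10))
        trf = reference.integrate_gpe(y0, np.zeros(nf), DT / 10, nf, pp_gpe)
        assert rate == pytest.approx(rate_from_trace(trf[:, 0], DT / 10),
                                     rel=0.05)

    def test_silenced_by_strong_inhibition(self, pp_gpe):
        y0 = neurons.gpe_init(pp_gpe)
        n = int(500 / DT)
        tr = reference.integrate_gpe(y0, np.full(n, 20.0), DT, n, pp_gpe)
        # outward current of 20 uA/cm^2: no threshold crossings in 500 ms
        assert len(reference.upward_crossings(tr[int(50 / DT):, 0],
                                              -10.0, DT)) == 0

    def test_gating_derivatives_zero_when_clamped(self, pp_gpe):
        v0 = -62.0
        y = neurons.gpe_init(pp_gpe, v0=v0)
        dy = neurons.gpe_rhs(y, 0.0, pp_gpe)
        assert np.allclose(dy[1:4], 0.0, atol=1e-10)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            gpe_derivatives(GPeState(ca=-1.0))


class TestDensityTable:
    def test_default_densities_and_conversion(self):
        table = ChannelDensityTable.from_params(default_params())
        assert table.g_na == {"ais": 90.0, "node": 200.0,
                              "collateral": 533.0, "internode": 500.0}
        assert table.g_kd["internode"] == 0.0
        # 1 pS/um^2 == 0.1 mS/cm^2 exactly
        g_na, g_k, g_kd, g_leak = table.row("node")
        assert g_na == pytest.approx(20.0)
        assert g_leak == pytest.approx(0.023)
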
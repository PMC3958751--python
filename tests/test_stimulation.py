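"""Pulse-train, point-source field and cable-coupling tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsnet.stimulation import (DBSSpec, Electrode, cable_drive,
                                dbs_current, extracellular_potential,
                                frequency_to_spec, pulse_onset_times)


class TestDBSCurrent:
    SPEC = DBSSpec(i_d=2.5, rho_d=1000.0 / 130.0, delta_d=0.06)

    def test_outside_window_is_zero(self):
        assert dbs_current(1.0, self.SPEC) == 0.0

    def test_inside_window_is_amplitude(self):
        # the active window within each period is (rho/2 - delta, rho/2]
        rho = self.SPEC.rho_d
        t = rho / 2.0 - 0.03
        assert dbs_current(t, self.SPEC) == pytest.approx(2.5)
        assert dbs_current(t + rho, self.SPEC) == pytest.approx(2.5)

    def test_window_boundaries_by_dense_sampling(self):
        rho, delta = self.SPEC.rho_d, self.SPEC.delta_d
        t = np.linspace(0.0, rho, 200001, endpoint=False)
        active = dbs_current(t, self.SPEC) > 0
        frac = active.mean()
        assert frac == pytest.approx(delta / rho, rel=2e-3)
        lo = t[active].min()
        hi = t[active].max()
        assert lo == pytest.approx(rho / 2 - delta, abs=rho / 200000 * 2)
        assert hi == pytest.approx(rho / 2, abs=rho / 200000 * 2)

    def test_duty_cycle_integral(self):
        # integral of |waveform| over one period equals i_d * delta_d
        rho = self.SPEC.rho_d
        t = np.linspace(0.0, rho, 4000001, endpoint=False)
        integral = np.trapezoid(np.abs(dbs_current(t, self.SPEC)), t)
        assert integral / (self.SPEC.i_d * self.SPEC.delta_d) == \
            pytest.approx(1.0, abs=1e-3)

    @given(freq=st.floats(5.0, 300.0))
    @settings(max_examples=30, deadline=None)
    def test_pulse_count_over_one_second(self, freq):
        spec = frequency_to_spec(freq, 1.0, 60.0)
        n = len(pulse_onset_times(spec, 1000.0))
        assert abs(n - round(freq)) <= 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DBSSpec(i_d=1.0, rho_d=1.0, delta_d=1.5)
        with pytest.raises(ValueError):
            dbs_current(-1.0, self.SPEC)


class TestExtracellularPotential:
    def test_closed_form_value(self):
        # 2.5 mA, sigma = 0.2 S/m, r = 1 mm -> ~0.9947 V
        el = Electrode(position=np.zeros(3), sigma=0.2)
        v = extracellular_potential(np.array([1000.0, 0.0, 0.0]), 2.5, el)
        expected_mv = 2.5e-3 / (4 * np.pi * 0.2 * 1e-3) * 1e3
        assert v == pytest.approx(expected_mv, rel=1e-12)

    @given(r=st.floats(10.0, 5000.0), i=st.floats(-5.0, 5.0),
           sigma=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_distance_law(self, r, i, sigma):
        el = Electrode(sigma=sigma)
        v1 = extracellular_potential(np.array([r, 0.0, 0.0]), i, el)
        v2 = extracellular_potential(np.array([2 * r, 0.0, 0.0]), i, el)
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-9)

    def test_zero_current_zero_potential(self):
        pts = np.random.default_rng(0).uniform(-500, 500, (20, 3))
        assert np.all(extracellular_potential(pts, 0.0) == 0.0)

    def test_superposition_of_two_sources(self):
        p = np.array([300.0, 100.0, -50.0])
        e1 = Electrode(position=np.array([0.0, 0.0, 0.0]))
        e2 = Electrode(position=np.array([500.0, 0.0, 0.0]))
        v_sum = (extracellular_potential(p, 1.3, e1)
                 + extracellular_potential(p, -0.7, e2))
        # superposition: fields of independent sources add linearly
        v_each = extracellular_potential(p, 1.0, e1) * 1.3 \
            + extracellular_potential(p, 1.0, e2) * -0.7
        assert v_sum == pytest.approx(v_each, rel=1e-12)

    def test_singularity_raises(self):
        with pytest.raises(ValueError):
            extracellular_potential(np.zeros(3), 1.0, Electrode())


class TestCableDrive:
    def test_uniform_field_contributes_nothing(self):
        vm = np.full(12, -70.0)
        base = cable_drive(vm, np.zeros(12), ga=1.0, cm=1.0)
        shifted = cable_drive(vm, np.full(12, 123.4), ga=1.0, cm=1.0)
        assert shifted == pytest.approx(base)

    def test_linear_gradient_activates_only_ends(self):
        vm = np.full(10, -70.0)
        ve = np.linspace(0.0, 90.0, 10)
        out = cable_drive(vm, ve, ga=2.0, cm=1.0) \
            - cable_drive(vm, np.zeros(10), ga=2.0, cm=1.0)
        assert np.allclose(out[1:-1], 0.0, atol=1e-12)
        assert out[0] > 0 and out[-1] < 0

    def test_linear_in_field(self):
        rng = np.random.default_rng(3)
        vm = rng.normal(-70, 5, 15)
        ve = rng.normal(0, 50, 15)
        a = cable_drive(vm, 2.0 * ve, 1.5, 1.0)
        b = cable_drive(vm, ve, 1.5, 1.0)
        c = cable_drive(vm, np.zeros(15), 1.5, 1.0)
        assert a - c == pytest.approx(2.0 * (b - c), rel=1e-10)

    def test_point_source_profile_matches_bruteforce(self):
        # activating-function profile along a straight cable 100 um from
        # a point source carrying a 2.1 mA pulse
        el = Electrode()
        x = np.arange(20) * 50.0 - 475.0
        pts = np.stack([np.full(20, 100.0), np.zeros(20), x], axis=1)
        ve = extracellular_potential(pts, 2.1, el)
        vm = np.full(20, -70.0)
        out = cable_drive(vm, ve, ga=3.0, cm=1.0) \
            - cable_drive(vm, np.zeros(20), ga=3.0, cm=1.0)
        brute = np.zeros(20)
        brute[1:-1] = 3.0 * (ve[:-2] - 2 * ve[1:-1] + ve[2:])
        brute[0] = 3.0 * (ve[1] - ve[0])
        brute[-1] = 3.0 * (ve[-2] - ve[-1])
        assert out == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cable_drive(np.zeros(5), np.zeros(6), 1.0, 1.0)


class TestFrequencyToSpec:
    @pytest.mark.parametrize("freq,expected_rho", [(130.0, 1000.0 / 130.0),
                                                   (20.0, 50.0)])
    def test_period_is_reciprocal(self, freq, expected_rho):
        spec = frequency_to_spec(freq, 2.5, 60.0)
        assert spec.rho_d == pytest.approx(expected_rho)

    def test_high_frequency_stimulus_parameters(self):
        spec = frequency_to_spec(130.0, 2.5, 60.0)
        assert spec.i_d == 2.5
        assert spec.delta_d == pytest.approx(0.06)
        assert spec.frequency_hz == pytest.approx(130.0)

    def test_pulse_width_must_fit_period(self):
        with pytest.raises(ValueError):
            frequency_to_spec(500.0, 1.0, 3000.0)
        with pytest.raises(ValueError):
            frequency_to_spec(-10.0, 1.0, 60.0)
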
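"""Experiment-layer tests: beta drive, calibration plumbing, sweeps."""

import numpy as np
import pytest

from dbsnet import analysis
from dbsnet.engine import NetworkModel
from dbsnet.experiments import (ParkinsonianConfig, SweepSpec,
                                aggregate_sweep, frequency_sweep,
                                generate_beta_drive, run_figure_experiment)
from dbsnet.params import default_params, merge_params

TINY = {"network": {"n_cortical": 6, "n_interneuron": 6, "n_stn": 12,
                    "n_gpe": 6}}


class TestParkinsonianConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParkinsonianConfig(cortex_stn_gain=1.0)
        with pytest.raises(ValueError):
            ParkinsonianConfig(gpe_gpe_gain=1.2)
        with pytest.raises(ValueError):
            ParkinsonianConfig(stn_gpe_gain=0.9)

    def test_override_tree_shape(self):
        cfg = ParkinsonianConfig()
        tree = cfg.as_param_override()
        assert tree["parkinsonian"]["enabled"]
        assert tree["beta_drive"]["frequency_hz"] == 20.0


class TestBetaDrive:
    def test_seed_reproducible(self):
        a = generate_beta_drive(20.0, 4.5, 2.0, seed=5, duration_ms=100.0,
                                n_neurons=4)
        b = generate_beta_drive(20.0, 4.5, 2.0, seed=5, duration_ms=100.0,
                                n_neurons=4)
        assert np.array_equal(a, b)
        c = generate_beta_drive(20.0, 4.5, 2.0, seed=6, duration_ms=100.0,
                                n_neurons=4)
        assert not np.array_equal(a, c)

    def test_half_rectified_and_periodic(self):
        d = generate_beta_drive(20.0, 4.5, 0.0, seed=0, duration_ms=100.0,
                                n_neurons=2)
        assert d.min() >= 0.0
        assert d.max() == pytest.approx(4.5, rel=1e-3)
        # period 50 ms at 20 Hz
        assert np.allclose(d[:, :5000], d[:, 5000:10000], atol=1e-9)

    def test_out_of_band_frequency_warns(self):
        with pytest.warns(UserWarning):
            generate_beta_drive(8.0, 4.5, 2.0, seed=0, duration_ms=10.0,
                                n_neurons=2)

    def test_matches_engine_internal_drive(self):
        # the engine's analytic drive and the generator agree
        p = merge_params(default_params(), TINY)
        model = NetworkModel(p, seed=5)
        d = generate_beta_drive(
            p["beta_drive"]["frequency_hz"], p["beta_drive"]["amplitude"],
            p["beta_drive"]["jitter_ms"], seed=5, duration_ms=10.0,
            n_neurons=6)
        t = np.arange(1000) * 0.01
        expected = p["beta_drive"]["amplitude"] * np.maximum(
            0.0, np.sin(model.beta_omega * t[None, :]
                        + model.beta_phase[:, None]))
        assert np.allclose(d, expected)

    def test_zero_amplitude_silences_cortex(self):
        p = merge_params(default_params(),
                         {**TINY, "beta_drive": {"amplitude": 0.0}})
        model = NetworkModel(p, seed=2)
        res, _ = model.simulate(400.0)
        assert len(res.spikes["cortex"][1]) == 0

    def test_cortical_population_beta_peak_in_band(self):
        # default parkinsonian drive: the cortical population signal has
        # its low-frequency spectral peak inside 13-30 Hz
        p = merge_params(default_params(), TINY)
        model = NetworkModel(p, seed=3)
        _, st = model.simulate(300.0)
        res, _ = model.simulate(1500.0, state=st, record=("cortex_soma",))
        sig, fs = analysis.population_signal(res, "cortex")
        sig, fs = analysis.decimate_signal(sig, fs)
        psd = analysis.welch_psd(sig, fs)
        mask = (psd.freqs > 3.0) & (psd.freqs <= 35.0)
        peak = psd.freqs[mask][np.argmax(psd.power[mask])]
        assert 13.0 <= peak <= 30.0


class TestSweepSpec:
    def test_requires_off_reference(self):
        with pytest.raises(ValueError):
            SweepSpec(frequencies=(10.0, 130.0))

    def test_figure_protocol_ids(self):
        with pytest.raises(KeyError):
            run_figure_experiment("fig12")


class TestSweepSmallScale:
    """Structural checks of the sweep machinery on a tiny network."""

    @pytest.fixture(scope="class")
    def sweep_df(self):
        spec = SweepSpec(frequencies=(0.0, 130.0), modes=("antidromic",),
                         n_repeats=2, base_seed=7, settle_ms=200.0,
                         off_ms=400.0, dbs_ms=400.0, spectral=False)
        return frequency_sweep(spec, params=TINY)

    def test_row_layout(self, sweep_df):
        assert len(sweep_df) == 4   # 2 repeats x (off + 130 Hz)
        assert set(sweep_df["frequency_hz"]) == {0.0, 130.0}

    def test_metrics_present_for_dbs_rows(self, sweep_df):
        on = sweep_df[sweep_df["frequency_hz"] > 0]
        assert on["antidromic_prob"].notna().all()
        assert (on["antidromic_prob"] >= 0).all()
        assert (on["antidromic_prob"] <= 1).all()

    def test_aggregate_shape(self, sweep_df):
        agg = aggregate_sweep(sweep_df)
        assert len(agg) == 2
        assert "antidromic_prob_mean" in agg.columns

    def test_determinism(self):
        spec = SweepSpec(frequencies=(0.0, 130.0), modes=("antidromic",),
                         n_repeats=1, base_seed=7, settle_ms=100.0,
                         off_ms=200.0, dbs_ms=200.0, spectral=False)
        a = frequency_sweep(spec, params=TINY)
        b = frequency_sweep(spec, params=TINY)
        on_a = a[a["frequency_hz"] > 0]["antidromic_prob"].iloc[0]
        on_b = b[b["frequency_hz"] > 0]["antidromic_prob"].iloc[0]
        assert on_a == on_b


class TestCalibration:
    """Parkinsonian calibration at reduced scale."""

    @pytest.fixture(scope="class")
    def calibrated(self):
        from dbsnet.experiments import calibrate_parkinsonian
        return calibrate_parkinsonian(params=TINY, seed=4,
                                      target_ratio=2.0,
                                      multipliers=(1.5, 2.0, 3.0),
                                      settle_ms=300.0, epoch_ms=800.0)

    def test_accepted_peak_in_beta_band(self, calibrated):
        cfg, report = calibrated
        accepted = report[report["accepted"]]
        assert len(accepted) == 1
        assert 13.0 <= accepted["peak_hz"].iloc[0] <= 30.0
        assert cfg.cortex_stn_gain == accepted["cortex_stn_gain"].iloc[0]

    def test_normal_state_not_accepted(self, calibrated):
        _, report = calibrated
        base = report[report["cortex_stn_gain"] == 1.0]
        assert not base["accepted"].any()
        assert (report["ratio"] >= report["ratio"].iloc[0]).all()

    def test_repeat_same_seed_identical(self, calibrated):
        from dbsnet.experiments import calibrate_parkinsonian
        cfg, _ = calibrated
        cfg2, _ = calibrate_parkinsonian(params=TINY, seed=4,
                                         target_ratio=2.0,
                                         multipliers=(1.5, 2.0, 3.0),
                                         settle_ms=300.0, epoch_ms=800.0)
        assert cfg2 == cfg
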
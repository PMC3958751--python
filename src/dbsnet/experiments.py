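"""Canned experiment protocols: parkinsonian calibration, frequency
sweeps and the standard figure-style experiments.

The analysis protocol for every condition is: a settling transient
(discarded), a DBS-off epoch of 1 s immediately preceding stimulus
onset, and a 1 s DBS-on epoch.  Conditions sharing a seed and mode also
share the pre-stimulus network state, which is simulated once and
snapshotted.  Repeats use different seeds for the network geometry and
noise streams while sharing the calibrated gain configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .engine import NetworkModel
from .params import default_params, merge_params
from .stimulation import frequency_to_spec

__all__ = ["ParkinsonianConfig", "SweepSpec", "generate_beta_drive",
           "calibrate_parkinsonian", "frequency_sweep",
           "run_figure_experiment", "run_condition", "CalibrationError"]

DEFAULT_SETTLE_MS = 1000.0
DEFAULT_OFF_MS = 1000.0
DEFAULT_DBS_MS = 1000.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class ParkinsonianConfig:
    """Dopamine-depleted network state: cortical beta drive plus gain
    multipliers relative to the normal state."""
    beta_frequency_hz: float = 20.0
    beta_amplitude: float = 4.5
    beta_jitter_ms: float = 2.0
    cortex_stn_gain: float = 3.0
    gpe_gpe_gain: float = 0.5
    stn_gpe_gain: float = 1.5
    gpe_stn_gain: float = 1.5

    def __post_init__(self):
        if not self.cortex_stn_gain > 1.0:
            raise ValueError("cortex->STN gain multiplier must exceed 1")
        if not self.gpe_gpe_gain < 1.0:
            raise ValueError("GPe->GPe gain multiplier must be below 1")
        if self.stn_gpe_gain <= 1.0 or self.gpe_stn_gain <= 1.0:
            raise ValueError("STN<->GPe gain multipliers must exceed 1")

    def as_param_override(self) -> dict:
        return {
            "beta_drive": {"frequency_hz": self.beta_frequency_hz,
                           "amplitude": self.beta_amplitude,
                           "jitter_ms": self.beta_jitter_ms},
            "parkinsonian": {"cortex_stn_gain": self.cortex_stn_gain,
                             "gpe_gpe_gain": self.gpe_gpe_gain,
                             "stn_gpe_gain": self.stn_gpe_gain,
                             "gpe_stn_gain": self.gpe_stn_gain,
                             "enabled": True},
        }


@dataclass
class SweepSpec:
    """DBS frequency-sweep specification.

    ``frequencies`` must include 0 (the DBS-off reference).
    """
    frequencies: tuple = (0.0, 10.0, 20.0, 50.0, 130.0, 200.0, 250.0)
    amplitude_ma: float = 2.1
    pulse_width_us: float = 60.0
    modes: tuple = ("both", "orthodromic", "antidromic")
    n_repeats: int = 5
    base_seed: int = 0
    settle_ms: float = DEFAULT_SETTLE_MS
    off_ms: float = DEFAULT_OFF_MS
    dbs_ms: float = DEFAULT_DBS_MS
    spectral: bool = True       # record traces and compute band powers

    def __post_init__(self):
        if 0.0 not in tuple(self.frequencies):
            raise ValueError("the sweep must include the 0 Hz (DBS off) "
                             "reference condition")


def generate_beta_drive(frequency_hz: float, amplitude: float,
                        jitter_ms: float, seed: int, duration_ms: float,
                        n_neurons: int = 100, dt: float = 0.01
                        ) -> np.ndarray:
    """Per-neuron injected beta-drive current series (uA/cm^2).

    Half-rectified sinusoid common to the population with a small
    per-neuron phase jitter, identical to the drive the engine applies
    internally (same seeding scheme).
    """
    if not (13.0 <= frequency_hz <= 30.0):
        warnings.warn(f"drive frequency {frequency_hz} Hz lies outside the "
                      f"beta band (13-30 Hz)", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(1,)))
    omega = 2.0 * np.pi * frequency_hz / 1000.0
    phase = omega * rng.normal(0.0, jitter_ms, n_neurons)
    t = np.arange(int(round(duration_ms / dt))) * dt
    return amplitude * np.maximum(0.0, np.sin(omega * t[None, :]
                                              + phase[:, None]))


# ----------------------------------------------------------------------


def _condition_metrics(res_off, res_on, n_cx, n_stn, freq, window_ms,
                       spectral, beta_lo, beta_hi, halfwidth):
    """Metrics for one (off epoch, on epoch) pair."""
    out = {}
    if res_on is not None and len(res_on.pulse_times) > 0:
        ids, times = res_on.spikes["cortex"]
        stats = analysis.antidromic_probability(
            ids, times, res_on.pulse_times, window=window_ms,
            n_neurons=n_cx, train_duration_ms=res_on.duration)
        out["antidromic_prob"] = stats.mean_prob
        out["antidromic_rate_hz"] = stats.mean_rate_hz
        out["antidromic_prob_min"] = float(stats.prob.min())
        sids, stimes = res_on.spikes["stn"]
        _, locked = analysis.entrainment_check(
            sids, stimes, res_on.pulse_times, window=5.0, n_neurons=n_stn)
        out["stn_entrainment"] = locked
    if spectral:
        for pop in ("stn", "cortex"):
            sig, fs = analysis.population_signal(res_off, pop)
            sig, fs = analysis.decimate_signal(sig, fs)
            psd = analysis.welch_psd(sig, fs)
            out[f"beta_power_off_{pop}"] = analysis.band_power(
                psd, beta_lo, beta_hi).power
            epoch = res_on if res_on is not None else res_off
            sig, fs = analysis.population_signal(epoch, pop)
            sig, fs = analysis.decimate_signal(sig, fs)
            psd = analysis.welch_psd(sig, fs)
            out[f"beta_power_on_{pop}"] = analysis.band_power(
                psd, beta_lo, beta_hi).power
            if freq > 0 and pop == "stn":
                lo = max(freq - halfwidth, psd.freqs[0])
                hi = min(freq + halfwidth, psd.freqs[-1])
                out["stim_band_power_stn"] = analysis.band_power(
                    psd, lo, hi).power
    return out


def run_condition(model: NetworkModel, pre_state, freq: float,
                  amplitude_ma: float, pulse_width_us: float,
                  dbs_ms: float, record: tuple = (), seed: int | None = None):
    """Run the 1 s (default) DBS-on epoch of one condition from a shared
    pre-stimulus snapshot; freq == 0 runs a stimulus-free epoch."""
    dbs = None
    if freq > 0:
        dbs = frequency_to_spec(freq, amplitude_ma, pulse_width_us,
                                onset=pre_state.t)
    res, st = model.simulate(dbs_ms, dbs=dbs, state=pre_state,
                             record=record, noise_seed=seed)
    return res, st


def frequency_sweep(spec: SweepSpec, params: dict | None = None,
                    progress: bool = False) -> pd.DataFrame:
    """Run the full frequency x mode sweep and return per-run metrics.

    One row per (mode, frequency, repeat); aggregate with
    :func:`aggregate_sweep`.  Deterministic for a given spec and params.
    """
    p = merge_params(default_params(), params or {})
    an = p["analysis"]
    record = ("cortex_soma", "stn") if spec.spectral else ()
    rows = []
    freqs = [f for f in spec.frequencies if f > 0]
    for rep in range(spec.n_repeats):
        seed = spec.base_seed + rep
        for mode in spec.modes:
            model = NetworkModel(p, seed=seed, mode=mode)
            # shared pre-stimulus trajectory: settle, then the off epoch
            _, st = model.simulate(spec.settle_ms, noise_seed=seed)
            res_off, st = model.simulate(spec.off_ms, state=st,
                                         record=record,
                                         noise_seed=seed + 7919)
            n_cx = model.graph.populations["cortex"]
            n_stn = model.graph.populations["stn"]
            base = {"mode": mode, "repeat": rep, "seed": seed}
            m_off = _condition_metrics(
                res_off, None, n_cx, n_stn, 0.0, an["antidromic_window"],
                spec.spectral, an["beta_lo"], an["beta_hi"],
                an["stim_band_halfwidth"])
            rows.append({**base, "frequency_hz": 0.0, **m_off})
            for freq in freqs:
                res_on, _ = run_condition(model, st, freq,
                                          spec.amplitude_ma,
                                          spec.pulse_width_us, spec.dbs_ms,
                                          record=record,
                                          seed=seed + 104729 + int(freq))
                m = _condition_metrics(
                    res_off, res_on, n_cx, n_stn, freq,
                    an["antidromic_window"], spec.spectral, an["beta_lo"],
                    an["beta_hi"], an["stim_band_halfwidth"])
                rows.append({**base, "frequency_hz": freq, **m})
                if progress:
                    print(f"  mode={mode} f={freq:g} Hz rep={rep} done")
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD over repeats for every numeric metric."""
    metrics = [c for c in df.columns
               if c not in ("mode", "repeat", "seed", "frequency_hz")]
    g = df.groupby(["mode", "frequency_hz"])[metrics]
    agg = g.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


# ----------------------------------------------------------------------


def calibrate_parkinsonian(params: dict | None = None, seed: int = 0,
                           target_ratio: float = 3.0,
                           multipliers: tuple = (1.5, 2.0, 3.0, 4.0),
                           settle_ms: float = 500.0,
                           epoch_ms: float = 1000.0):
    """Scalar search over the cortex->STN gain multiplier until the
    DBS-off STN beta power exceeds the normal state's by
    ``target_ratio`` with the spectral peak inside the beta band.

    The normal-state reference uses the same drive with a quarter-
    period phase jitter (a desynchronized rhythm); the synchronized
    drive plus the gain multipliers constitute the dopamine-depleted
    state.  Returns ``(ParkinsonianConfig, report)``; the report lists
    every tried multiplier.  Deterministic given the seed.
    """
    p = merge_params(default_params(), params or {})
    an = p["analysis"]
    # the normal-state reference keeps the same per-neuron drive but
    # desynchronized (phase jitter of a quarter period), since the
    # synchronized rhythm is itself part of the dopamine-depleted state
    desync_ms = 250.0 / p["beta_drive"]["frequency_hz"]

    def stn_beta(mult_enabled, mult):
        q = merge_params(p, {"parkinsonian": {"enabled": mult_enabled,
                                              "cortex_stn_gain": mult}})
        if not mult_enabled:
            q = merge_params(q, {"beta_drive": {"jitter_ms": desync_ms}})
        model = NetworkModel(q, seed=seed)
        _, st = model.simulate(settle_ms, noise_seed=seed)
        res, _ = model.simulate(epoch_ms, state=st, record=("stn",),
                                noise_seed=seed + 7919)
        sig, fs = analysis.population_signal(res, "stn")
        sig, fs = analysis.decimate_signal(sig, fs)
        psd = analysis.welch_psd(sig, fs)
        bp = analysis.band_power(psd, an["beta_lo"], an["beta_hi"]).power
        # peak of the low-frequency fundamental: the raw population-Vm
        # spectrum of burst-locked spiking carries harmonics of the
        # rhythm, so the search is restricted to below 35 Hz
        mask = (psd.freqs > 3.0) & (psd.freqs <= 35.0)
        peak = float(psd.freqs[mask][np.argmax(psd.power[mask])])
        return bp, peak

    normal_bp, _ = stn_beta(False, 1.0)
    report = [{"cortex_stn_gain": 1.0, "stn_beta_power": normal_bp,
               "ratio": 1.0, "peak_hz": np.nan, "accepted": False}]
    for mult in multipliers:
        bp, peak = stn_beta(True, mult)
        ratio = bp / normal_bp if normal_bp > 0 else np.inf
        ok = (ratio >= target_ratio
              and an["beta_lo"] <= peak <= an["beta_hi"])
        report.append({"cortex_stn_gain": mult, "stn_beta_power": bp,
                       "ratio": ratio, "peak_hz": peak, "accepted": ok})
        if ok:
            pk = p["parkinsonian"]
            bd = p["beta_drive"]
            cfg = ParkinsonianConfig(
                beta_frequency_hz=bd["frequency_hz"],
                beta_amplitude=bd["amplitude"],
                beta_jitter_ms=bd["jitter_ms"],
                cortex_stn_gain=mult,
                gpe_gpe_gain=pk["gpe_gpe_gain"],
                stn_gpe_gain=pk["stn_gpe_gain"],
                gpe_stn_gain=pk["gpe_stn_gain"])
            return cfg, pd.DataFrame(report)
    raise CalibrationError(
        "no multiplier reached the calibration target; tried:\n"
        + pd.DataFrame(report).to_string(index=False))


# ----------------------------------------------------------------------

FIGURE_PROTOCOLS = {
    "fig5": {"modes": ("both",), "frequencies": (0.0, 20.0, 130.0),
             "amplitude_ma": 2.5, "spectral": False},
    "fig6": {"modes": ("both",), "frequencies": (0.0, 20.0, 130.0),
             "amplitude_ma": 2.5, "spectral": True},
    "fig7": {"modes": ("both", "orthodromic", "antidromic"),
             "frequencies": (0.0, 20.0, 50.0, 130.0), "amplitude_ma": 2.1,
             "spectral": True},
    "fig8": {"modes": ("orthodromic",), "frequencies": (0.0, 130.0),
             "amplitude_ma": 2.1, "spectral": True, "cable": True},
    "fig9": {"modes": ("antidromic",),
             "frequencies": (0.0, 10.0, 50.0, 130.0, 200.0, 250.0),
             "amplitude_ma": 2.1, "spectral": False},
}


def run_figure_experiment(figure: str, params: dict | None = None,
                          overrides: dict | None = None,
                          n_repeats: int = 5, base_seed: int = 0,
                          progress: bool = False) -> dict:
    """Run the canned protocol reproducing one of the standard figures.

    Returns a dict with the raw per-run metric table (``metrics``), the
    aggregate over repeats (``aggregate``) and, for the collateral
    experiment, per-compartment beta powers (``collateral_beta``).
    """
    if figure not in FIGURE_PROTOCOLS:
        raise KeyError(f"unknown figure id {figure!r}; expected one of "
                       f"{sorted(FIGURE_PROTOCOLS)}")
    proto = dict(FIGURE_PROTOCOLS[figure])
    cable = proto.pop("cable", False)
    spec = SweepSpec(frequencies=tuple(proto["frequencies"]),
                     modes=tuple(proto["modes"]),
                     amplitude_ma=proto["amplitude_ma"],
                     spectral=proto["spectral"], n_repeats=n_repeats,
                     base_seed=base_seed, **(overrides or {}))
    df = frequency_sweep(spec, params=params, progress=progress)
    out = {"figure": figure, "metrics": df, "aggregate": aggregate_sweep(df)}
    if cable:
        out["collateral_beta"] = collateral_beta_profile(
            params=params, seed=base_seed,
            freq=max(spec.frequencies), amplitude_ma=spec.amplitude_ma,
            pulse_width_us=spec.pulse_width_us, settle_ms=spec.settle_ms,
            dbs_ms=spec.dbs_ms)
    return out


def collateral_beta_profile(params: dict | None = None, seed: int = 0,
                            freq: float = 130.0, amplitude_ma: float = 2.1,
                            pulse_width_us: float = 60.0,
                            settle_ms: float = DEFAULT_SETTLE_MS,
                            dbs_ms: float = DEFAULT_DBS_MS,
                            neuron: int = 0) -> pd.DataFrame:
    """Beta-band power of each collateral compartment of one neuron
    under orthodromic-only DBS (the along-collateral suppression
    profile)."""
    p = merge_params(default_params(), params or {})
    an = p["analysis"]
    model = NetworkModel(p, seed=seed, mode="orthodromic")
    _, st = model.simulate(settle_ms, noise_seed=seed)
    dbs = frequency_to_spec(freq, amplitude_ma, pulse_width_us, onset=st.t)
    res, _ = model.simulate(dbs_ms, dbs=dbs, state=st, record=("cable",),
                            cable_record_neuron=neuron,
                            noise_seed=seed + 7919)
    cable = res.traces["cable"]
    dt_rec = res.trace_times[1] - res.trace_times[0]
    fs = 1000.0 / dt_rec
    rows = []
    for j, c in enumerate(model.morph.collateral_idx):
        sig = cable[:, c] - cable[:, c].mean()
        sig_d, fs_d = analysis.decimate_signal(sig, fs)
        psd = analysis.welch_psd(sig_d, fs_d)
        bp = analysis.band_power(psd, an["beta_lo"], an["beta_hi"]).power
        rows.append({"compartment": j + 1, "beta_power": bp})
    return pd.DataFrame(rows)
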
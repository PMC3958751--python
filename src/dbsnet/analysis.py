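"""Spike statistics and spectral analysis.

Beta-band (13-30 Hz) power of population membrane signals is estimated
with Welch's averaged-periodogram method on the sum of somatic membrane
potentials across a population (mean-subtracted), after anti-aliased
decimation to 1 kHz.  Stimulus-locked metrics quantify orthodromic
entrainment of STN firing and the probability of antidromic cortical
firing per DBS pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["PSDResult", "BandPower", "AntidromicStats", "population_signal",
           "decimate_signal", "welch_psd", "band_power",
           "antidromic_probability", "entrainment_check"]


@dataclass
class PSDResult:
    """Power spectral density estimate and its estimator parameters."""
    freqs: np.ndarray        # Hz
    power: np.ndarray        # signal-units^2 / Hz
    fs: float
    nperseg: int
    noverlap: int
    window: str = "hann"
    source: str = ""

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))


@dataclass
class BandPower:
    """Integrated PSD over a frequency band."""
    lo: float
    hi: float
    power: float
    condition: str = ""


@dataclass
class AntidromicStats:
    """Per-neuron and population antidromic firing metrics."""
    prob: np.ndarray          # fraction of pulses answered, per neuron
    rate_hz: np.ndarray       # attributed spikes per second, per neuron
    window: float             # ms
    n_pulses: int
    mean_prob: float = field(init=False)
    mean_rate_hz: float = field(init=False)

    def __post_init__(self):
        self.mean_prob = float(np.mean(self.prob))
        self.mean_rate_hz = float(np.mean(self.rate_hz))


def population_signal(result, population: str) -> tuple[np.ndarray, float]:
    """Sum of somatic membrane potentials across a population.

    Returns ``(signal, fs)`` with the signal mean-subtracted and ``fs``
    in Hz.  Raises if the population's traces were not recorded.
    """
    key = "cortex_soma" if population in ("cortex", "cortex_soma") \
        else population
    if key not in result.traces:
        raise KeyError(
            f"no membrane traces recorded for {population!r}; rerun the "
            f"simulation with record=({key!r},)")
    arr = result.traces[key]
    sig = arr.sum(axis=1)
    sig = sig - sig.mean()
    dt_rec = (result.trace_times[1] - result.trace_times[0]
              if len(result.trace_times) > 1 else result.dt)
    return sig, 1000.0 / dt_rec


def decimate_signal(sig: np.ndarray, fs: float, fs_out: float = 1000.0
                    ) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation to approximately ``fs_out`` Hz."""
    factor = int(round(fs / fs_out))
    if factor <= 1:
        return np.asarray(sig, dtype=float), fs
    out = sps.decimate(np.asarray(sig, dtype=float), factor, ftype="fir",
                       zero_phase=True)
    return out, fs / factor


def welch_psd(sig: np.ndarray, fs: float, segment_s: float = 1.0,
              overlap: float = 0.5, source: str = "",
              detrend: str = "constant") -> PSDResult:
    """Welch PSD (Hann window, density scaling).

    The default is 1 s segments with 50 % overlap; if the signal is
    shorter than two segments but at least one, a single full-length
    segment (plain periodogram) is used; shorter signals raise.
    """
    sig = np.asarray(sig, dtype=float)
    nperseg = int(round(segment_s * fs))
    if len(sig) < nperseg:
        if len(sig) < 8:
            raise ValueError("signal too short for spectral estimation")
        nperseg = len(sig)
    noverlap = int(nperseg * overlap)
    freqs, power = sps.welch(sig, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=noverlap, detrend=detrend,
                             scaling="density")
    return PSDResult(freqs=freqs, power=power, fs=fs, nperseg=nperseg,
                     noverlap=noverlap, source=source)


def band_power(psd: PSDResult, lo: float, hi: float, condition: str = ""
               ) -> BandPower:
    """Trapezoidal integral of the PSD over [lo, hi] Hz."""
    if hi <= lo:
        raise ValueError(f"inverted band [{lo}, {hi}]")
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(f"band [{lo}, {hi}] outside the frequency grid "
                         f"[{psd.freqs[0]}, {psd.freqs[-1]}]")
    # include the exact band edges by interpolation
    grid = psd.freqs
    inside = (grid > lo) & (grid < hi)
    f = np.concatenate([[lo], grid[inside], [hi]])
    p = np.interp(f, grid, psd.power)
    return BandPower(lo=lo, hi=hi, power=float(np.trapezoid(p, f)),
                     condition=condition)


def _per_neuron_attribution(spike_ids, spike_times, pulse_times, window,
                            n_neurons):
    """Unique attribution: each spike is assigned to the most recent
    pulse no more than ``window`` ms before it; a pulse counts as
    answered when at least one spike is assigned to it.  Unique
    assignment avoids double counting in both directions (a spike can
    answer only one pulse, a pulse is answered at most once)."""
    pt = np.sort(np.asarray(pulse_times, dtype=float))
    n_pulses = len(pt)
    answered = np.zeros(n_neurons)
    attributed = np.zeros(n_neurons)
    ids = np.asarray(spike_ids)
    times = np.asarray(spike_times)
    for n in range(n_neurons):
        st = np.sort(times[ids == n])
        if len(st) == 0:
            continue
        j = np.searchsorted(pt, st, side="right") - 1
        valid = (j >= 0) & (st - pt[np.clip(j, 0, None)] <= window)
        attributed[n] = np.count_nonzero(valid)
        answered[n] = len(np.unique(j[valid]))
    return answered, attributed, n_pulses


def antidromic_probability(spike_ids, spike_times, pulse_times,
                           window: float = 10.0, n_neurons: int = 100,
                           train_duration_ms: float | None = None
                           ) -> AntidromicStats:
    """Antidromic firing probability per DBS pulse and attributed spike
    frequency.

    Each somatic spike is attributed to the most recent pulse no more
    than ``window`` ms before it; the probability is the number of
    answered pulses over the number of stimuli (the number of
    antidromic spikes over the number of stimuli, counting at most one
    spike per pulse).  The attributed spike frequency is the number of
    attributed spikes per second of pulse train.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if len(pulse_times) == 0:
        raise ValueError("no DBS pulses in the analysed window")
    if window <= 0:
        raise ValueError("attribution window must be positive")
    answered, attributed, n_pulses = _per_neuron_attribution(
        spike_ids, spike_times, pulse_times, window, n_neurons)
    if train_duration_ms is None:
        if n_pulses > 1:
            isi = np.median(np.diff(np.sort(pulse_times)))
            train_duration_ms = n_pulses * isi
        else:
            train_duration_ms = window
    return AntidromicStats(prob=answered / n_pulses,
                           rate_hz=attributed / (train_duration_ms / 1000.0),
                           window=window, n_pulses=n_pulses)


def entrainment_check(spike_ids, spike_times, pulse_times,
                      window: float = 5.0, n_neurons: int = 100
                      ) -> tuple[np.ndarray, float]:
    """Fraction of pulses followed by a spike within a fixed latency
    window, per neuron, and the population mean (locked fraction)."""
    pulse_times = np.asarray(pulse_times, dtype=float)
    if len(pulse_times) == 0:
        raise ValueError("no DBS pulses in the analysed window")
    if window <= 0:
        raise ValueError("latency window must be positive")
    answered, _, n_pulses = _per_neuron_attribution(
        spike_ids, spike_times, pulse_times, window, n_neurons)
    locked = answered / n_pulses
    return locked, float(np.mean(locked))
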
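"""Extracellular DBS: pulse trains, point-source fields, cable coupling.

The stimulus is a train of monophasic rectangular current pulses

    I_DBS(t) = i_D H(sin(2 pi t / rho_D)) [1 - H(sin(2 pi (t + delta_D) / rho_D))]

with Heaviside ``H`` (H(x) = 1 for x >= 0), interstimulus interval
``rho_D`` (ms), amplitude ``i_D`` (mA) and pulse width ``delta_D`` (ms).
Within each period the pulse occupies the half-open window
``(rho_D/2 - delta_D, rho_D/2]``.

The electrode is a point current source in a homogeneous, isotropic,
purely resistive medium of conductivity sigma, giving the quasistatic
potential V_e = I / (4 pi sigma r) at distance r.

Coupling into cable compartments follows the activating-function form:
the extracellular potentials sampled at compartment centers enter the
cable equation through the same second-difference operator as the
reduced membrane potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DBSSpec", "Electrode", "dbs_current", "pulse_onset_times",
           "extracellular_potential", "cable_drive", "frequency_to_spec"]


@dataclass
class DBSSpec:
    """Rectangular DBS pulse-train parameters.

    Attributes
    ----------
    i_d : pulse amplitude in mA.
    rho_d : interstimulus interval in ms (period of the train).
    delta_d : pulse width in ms; must satisfy 0 < delta_d < rho_d.
    onset, offset : ms; the train is gated to [onset, offset).
    """
    i_d: float = 2.5
    rho_d: float = 1000.0 / 130.0
    delta_d: float = 0.06
    onset: float = 0.0
    offset: float = np.inf

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_d < self.rho_d):
            raise ValueError(
                f"require 0 < delta_d < rho_d, got delta_d={self.delta_d}, "
                f"rho_d={self.rho_d}")
        if not np.isfinite(self.i_d):
            raise ValueError("pulse amplitude must be finite")

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.rho_d


@dataclass
class Electrode:
    """Point-source electrode position (um) and medium conductivity (S/m)."""
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma: float = 0.2

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.sigma <= 0:
            raise ValueError("medium conductivity sigma must be positive")


def _heaviside(x: np.ndarray | float):
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


def dbs_current(t, spec: DBSSpec):
    """Instantaneous DBS current (mA) at time(s) ``t`` (ms).

    Evaluates the Heaviside pulse-train expression literally; the result
    is periodic with period ``rho_d`` and the active window within each
    period has measure ``delta_d``.  Outside [onset, offset) the train
    is off.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tt = t - spec.onset
    w = 2.0 * np.pi / spec.rho_d
    val = (spec.i_d * _heaviside(np.sin(w * tt))
           * (1.0 - _heaviside(np.sin(w * (tt + spec.delta_d)))))
    gate = (t >= spec.onset) & (t < spec.offset)
    out = np.where(gate, val, 0.0)
    return float(out) if out.ndim == 0 else out


def pulse_onset_times(spec: DBSSpec, t_end: float) -> np.ndarray:
    """Onset times (ms) of every pulse with onset in [spec.onset, min(offset, t_end)).

    Each pulse occupies ``(rho_d/2 - delta_d, rho_d/2]`` within its period
    (relative to the train onset), so pulse k starts at
    ``onset + k rho_d + rho_d/2 - delta_d``.
    """
    first = spec.rho_d / 2.0 - spec.delta_d
    end = min(spec.offset, t_end) - spec.onset
    if end <= first:
        return np.empty(0)
    n = int(np.ceil((end - first) / spec.rho_d))
    k = np.arange(n)
    times = spec.onset + first + k * spec.rho_d
    return times[times < min(spec.offset, t_end)]


def extracellular_potential(points, current_ma: float,
                            electrode: Electrode | None = None):
    """Potential (mV) of a point source at ``points`` (um, shape (..., 3)).

    V_e = I / (4 pi sigma r) with r the Euclidean distance to the
    electrode.  Superposition over several sources can be obtained by
    summing calls.  Raises for points coincident with the source.
    """
    electrode = electrode or Electrode()
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    r_um = np.linalg.norm(pts - electrode.position, axis=-1)
    if np.any(r_um == 0.0):
        raise ValueError("extracellular potential is singular at the electrode")
    r_m = r_um * 1e-6
    v_volts = (current_ma * 1e-3) / (4.0 * np.pi * electrode.sigma * r_m)
    v_mv = v_volts * 1e3
    return float(v_mv[0]) if scalar else v_mv


def cable_drive(vm: np.ndarray, ve: np.ndarray, ga: float, cm: float
                ) -> np.ndarray:
    """dVm/dt contribution (mV/ms) of axial + extracellular coupling.

    For a uniform chain of compartments with axial conductance ``ga``
    (mS per unit membrane area, i.e. mS/cm^2) and capacitance ``cm``
    (uF/cm^2), interior compartment n receives

        (ga/cm) (V_{n-1} - 2 V_n + V_{n+1} + Ve_{n-1} - 2 Ve_n + Ve_{n+1})

    with ``V`` the reduced membrane potentials and ``Ve`` the
    extracellular potentials sampled at compartment centers.  End
    compartments use one-sided (sealed-end) differences.  The operator
    is linear in ``ve``: a uniform field contributes exactly zero and a
    linear gradient contributes only at the ends.
    """
    vm = np.asarray(vm, dtype=float)
    ve = np.asarray(ve, dtype=float)
    if vm.shape != ve.shape:
        raise ValueError(
            f"Vm and Ve must have matching lengths, got {vm.shape} vs {ve.shape}")
    tot = vm + ve
    out = np.zeros_like(tot)
    out[1:-1] = tot[:-2] - 2.0 * tot[1:-1] + tot[2:]
    out[0] = tot[1] - tot[0]
    out[-1] = tot[-2] - tot[-1]
    return (ga / cm) * out


def frequency_to_spec(frequency_hz: float, amplitude_ma: float,
                      pulse_width_us: float, onset: float = 0.0,
                      offset: float = np.inf) -> DBSSpec:
    """Build a :class:`DBSSpec` from frequency (Hz), amplitude (mA) and
    pulse width (us)."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    rho_d = 1000.0 / frequency_hz
    delta_d = pulse_width_us / 1000.0
    if delta_d >= rho_d:
        raise ValueError(
            f"pulse width {pulse_width_us} us does not fit in the "
            f"{rho_d:.3f} ms period")
    return DBSSpec(i_d=amplitude_ma, rho_d=rho_d, delta_d=delta_d,
                   onset=onset, offset=offset)
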
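"""Default model parameters and configuration handling.

All quantities use a consistent Hodgkin-Huxley unit system: mV, ms,
uA/cm^2, mS/cm^2, uF/cm^2, um.  Channel densities that the morphology
literature quotes in pS/um^2 are stored as such and converted with
1 pS/um^2 = 0.1 mS/cm^2.

The cell-kinetics blocks (regular-spiking cortical soma, cortical axon,
subthalamic and pallidal single-compartment models) collect published
parameterizations of those cell types into one versioned, overridable
defaults tree; every value can be replaced from a YAML/JSON config file.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

PS_PER_UM2_TO_MS_PER_CM2 = 0.1

#: Version tag of the default parameter set.  Bump when defaults change.
PARAMS_VERSION = "1.0"


def default_params() -> dict:
    """Return the full default parameter tree (deep copy, safe to mutate)."""
    return copy.deepcopy(_DEFAULTS)


_DEFAULTS: dict = {
    "version": PARAMS_VERSION,
    # ------------------------------------------------------------------
    # Regular-spiking cortical soma: minimal HH model with I_Na, I_Kd and
    # the slow non-inactivating K+ current I_M responsible for
    # spike-frequency adaptation.
    "soma": {
        "cm": 1.0,                 # uF/cm^2
        "g_na": 56.0,              # mS/cm^2
        "e_na": 50.0,              # mV
        "g_kd": 6.0,               # mS/cm^2
        "e_k": -90.0,              # mV
        "g_m": 0.075,              # mS/cm^2 (adaptation current)
        "tau_max_m": 608.0,        # ms, voltage-independent scale of tau_p
        "g_leak": 0.0205,          # mS/cm^2
        "e_leak": -70.3,           # mV
        "v_t": -56.2,              # mV, spike-threshold adjustment of rates
    },
    # ------------------------------------------------------------------
    # Cortical axon compartments (AIS, nodes, internodes, collateral).
    # Densities are the published table in pS/um^2; kinetics are
    # Traub-style Na/K rates shifted for axonal excitability plus a
    # rapidly activating, slowly inactivating D-type K+ current (Kd).
    "axon": {
        "cm": 1.0,                 # uF/cm^2 (bare membrane)
        "e_na": 50.0,
        "e_k": -90.0,
        "g_leak_ps_um2": 0.23,     # identical in every axon compartment
        "e_leak": -70.0,
        # Axonal Na gating (node-type): activation m (fast sigmoid) and
        # inactivation h with half-inactivation below rest, so that Na
        # is fully inactivated at depolarized potentials (no
        # persistent-Na plateau in the high-Na collateral).
        "na_theta_m": -46.0, "na_sigma_m": 7.0, "na_tau_m": 0.08,
        "na_theta_h": -58.0, "na_sigma_h": -7.0,
        "na_tau_h0": 0.4, "na_tau_h1": 25.0,
        "na_tau_h_theta": -55.0, "na_tau_h_sigma": 8.0,
        # the unmyelinated collateral carries a Na+ complement with
        # steeper, more complete inactivation (no depolarized plateau
        # despite its very high Na density) and fast recovery, so the
        # collateral follows high stimulus rates while the main axon
        # shows frequency-dependent invasion failure
        "na_theta_h_collateral": -62.0, "na_sigma_h_collateral": -6.0,
        "na_tau_h1_collateral": 6.0,
        # pS/um^2 per compartment kind
        "g_na_ps_um2": {"ais": 90.0, "node": 200.0, "collateral": 533.0,
                        "internode": 500.0},
        "g_k_ps_um2": {"ais": 120.0, "node": 30.0, "collateral": 10.0,
                       "internode": 50.0},
        "g_kd_ps_um2": {"ais": 6.0, "node": 3.0, "collateral": 10.0,
                        "internode": 0.0},
        # fast-rectifier gating (first-order sigmoid)
        "k_theta": -15.0, "k_sigma": 6.0, "k_tau": 1.0,
        # Kd gating (activation a, inactivation b)
        "kd_theta_a": -50.0, "kd_sigma_a": 10.0, "kd_tau_a": 2.0,     # ms
        "kd_theta_b": -75.0, "kd_sigma_b": -8.0, "kd_tau_b": 120.0,   # ms
        # Myelin is represented in the reduced single-cable way: the
        # specific capacitance and the voltage-gated conductances of
        # internodal compartments are divided by this wrap factor (leak
        # is left unscaled: the sheath still passes DC current).
        "myelin_factor": 40.0,
        "ri_ohm_cm": 30.0,         # axial resistivity
    },
    # ------------------------------------------------------------------
    # Cortical neuron morphology (um).
    "geometry": {
        "soma_l": 35.0, "soma_d": 25.0,
        "ais_l": 20.0, "ais_d": 1.2,
        "n_nodes": 10,
        "node_l": 2.0, "node_d": 0.5,
        "internode_l": 500.0, "internode_d": 1.4,
        "collateral_l": 500.0, "collateral_d": 0.5,
        "n_collateral_comps": 5,
    },
    # ------------------------------------------------------------------
    # Fast-spiking inhibitory interneuron (quadratic integrate-and-reset
    # family).  c is the printed after-spike reset value; a, b, d use the
    # fast-spiking parameterization of that model family.
    "interneuron": {
        "a": 0.1,
        "b": 0.2,
        "c": -65.0,   # mV after-spike reset
        "d": 2.0,
        "v_peak": 30.0,  # mV threshold of the reset rule
    },
    # ------------------------------------------------------------------
    # STN single-compartment model (plateau-potential formulation with
    # Na, K, A-type K, L-type Ca, T-type Ca, Ca-activated K and leak
    # currents plus an intracellular Ca pool, concentration in uM).
    "stn": {
        "cm": 1.0,
        "g_na": 49.0, "e_na": 60.0,
        "g_k": 57.0, "e_k": -90.0,
        "g_a": 5.0,
        "g_l_ca": 15.0, "e_ca": 140.0,
        "g_t": 5.0,
        "g_cak": 1.0,
        "g_leak": 0.35, "e_leak": -60.0,
        # x_inf = 1/(1+exp(-(V-theta)/sigma))
        "theta_m": -40.0, "sigma_m": 8.0,
        "theta_h": -45.5, "sigma_h": -6.4,
        "theta_n": -41.0, "sigma_n": 14.0,
        "theta_p": -56.0, "sigma_p": 6.7,
        "theta_q": -85.0, "sigma_q": -5.8,
        "theta_a": -45.0, "sigma_a": 14.7,
        "theta_b": -90.0, "sigma_b": -7.5,
        "theta_c": -30.6, "sigma_c": 5.0,
        "theta_d1": -60.0, "sigma_d1": -7.5,
        "theta_d2": 0.1, "sigma_d2": -0.02,   # Ca-dependent (uM)
        "theta_r": 0.17, "sigma_r": 0.08,     # Ca-dependent (uM)
        "tau_d2": 130.0, "tau_r": 2.0,
        "ca_alpha": 5.18e-3,   # uM cm^2 / (uA ms), influx scaling
        "ca_k": 2.0,           # 1/ms removal rate
        "i_app": 0.5,          # uA/cm^2; sets autonomous tonic rate ~15 Hz
    },
    # ------------------------------------------------------------------
    # GPe single-compartment model (pallidal formulation with leak, Na,
    # K, T-type Ca, Ca and afterhyperpolarization currents).
    "gpe": {
        "cm": 1.0,
        "g_l": 0.1, "v_l": -55.0,
        "g_k": 30.0, "v_k": -80.0,
        "g_na": 120.0, "v_na": 55.0,
        "g_t": 0.5,
        "g_ca": 0.15, "v_ca": 120.0,
        "g_ahp": 30.0,
        "theta_m": -37.0, "sigma_m": 10.0,
        "theta_h": -58.0, "sigma_h": -12.0,
        "theta_n": -50.0, "sigma_n": 14.0,
        "theta_r": -70.0, "sigma_r": -2.0,
        "theta_a": -57.0, "sigma_a": 2.0,
        "theta_s": -35.0, "sigma_s": 2.0,
        "tau_h0": 0.05, "tau_h1": 0.27, "theta_h_tau": -40.0, "sigma_h_tau": -12.0,
        "tau_n0": 0.05, "tau_n1": 0.27, "theta_n_tau": -40.0, "sigma_n_tau": -12.0,
        "phi_h": 0.05, "phi_n": 0.05, "phi_r": 1.0,
        "tau_r": 30.0,
        "k1_ahp": 30.0,
        "ca_eps": 1e-4,
        "ca_k": 20.0,
        "i_app": 1.0,          # uA/cm^2; autonomous tonic rate ~35 Hz
    },
    # ------------------------------------------------------------------
    # Synaptic pathways: alpha-function conductances, per-connection gain
    # (mS/cm^2 of postsynaptic membrane), reversal potential and rise time.
    "synapses": {
        "cortex->stn": {"gain": 0.08, "tau": 0.8, "e_rev": 0.0},
        "gpe->stn": {"gain": 0.15, "tau": 0.8, "e_rev": -85.0},
        "stn->gpe": {"gain": 0.06, "tau": 0.2, "e_rev": 0.0},
        "gpe->gpe": {"gain": 0.06, "tau": 0.86, "e_rev": -85.0},
        "cortex->interneuron": {"gain": 0.0012, "tau": 0.5, "e_rev": 0.0},
        "interneuron->cortex": {"gain": 0.005, "tau": 0.93, "e_rev": -80.0},
    },
    # ------------------------------------------------------------------
    # Membrane current noise, identical independent streams per neuron.
    "noise": {"sigma": 0.001},    # uA/cm^2 Gaussian white noise, mean 0
    # ------------------------------------------------------------------
    # Extracellular stimulation.
    "stim": {
        "sigma_s_per_m": 0.2,      # bulk tissue conductivity
        "electrode_xyz": [0.0, 0.0, 0.0],   # um
        # Direct pulse-locked depolarizing drive into each interneuron
        # during the stimulation window (models their activation through
        # cortical afferents); amplitude in the interneuron model's
        # current units, duration per pulse in ms.
        "interneuron_drive_amp": 60.0,
        "interneuron_drive_ms": 1.0,
        # pulse-locked interneuron drive latency: a fixed delay plus a
        # per-interneuron uniform jitter, modelling the polysynaptic
        # route through the cortical afferents.  The resulting 8-20 ms
        # latency places the inhibitory volley after the antidromic
        # somatic invasion of the same pulse.
        "interneuron_drive_delay_ms": 0.0,
        "interneuron_drive_jitter_ms": 12.0,
        # If true the extracellular field is also applied to main-axon
        # compartments; by default only the collateral (the stated DBS
        # target) sees the field and the main axon is treated as distant.
        "full_field": False,
    },
    # ------------------------------------------------------------------
    # Parkinsonian cortical beta drive: per-neuron half-rectified
    # sinusoidal current injected at the soma with small phase jitter so
    # the population fires synchronized beta bursts.
    "beta_drive": {
        "frequency_hz": 20.0,
        "amplitude": 4.5,        # uA/cm^2 peak
        "jitter_ms": 2.0,        # SD of per-neuron phase offset
    },
    # ------------------------------------------------------------------
    # Dopamine-depleted state: multiplicative gain factors relative to
    # the normal-state synaptic gains above.
    "parkinsonian": {
        "cortex_stn_gain": 3.0,
        "gpe_gpe_gain": 0.5,
        "stn_gpe_gain": 1.5,
        "gpe_stn_gain": 1.5,
        "enabled": True,
    },
    # ------------------------------------------------------------------
    # Network layout.
    "network": {
        "n_cortical": 100,
        "n_interneuron": 100,
        "n_stn": 100,
        "n_gpe": 100,
        "n_stn_per_collateral": 10,   # each collateral -> 10 nearest STN
        "n_gpe_to_stn": 1,            # nearest-GPe inhibition of each STN
        "n_stn_to_gpe": 2,            # each STN excites 2 closest GPe
        "n_gpe_to_gpe": 2,            # each GPe inhibited by 2 closest GPe
        # Collateral cloud around the electrode: axes parallel to z,
        # centers uniform in an annulus in the x-y plane (um).
        "collateral_r_min": 270.0,
        "collateral_r_max": 340.0,
        # uniform +-jitter of each collateral's axial (z) center, so the
        # synaptic terminals spread through the STN volume
        "collateral_z_jitter": 120.0,
        # STN and GPe nuclei as disjoint axis-aligned boxes (um):
        # [x0, x1, y0, y1, z0, z1]
        "stn_box": [-350.0, 350.0, -350.0, 350.0, 50.0, 450.0],
        "gpe_box": [700.0, 1400.0, -350.0, 350.0, 50.0, 450.0],
    },
    # ------------------------------------------------------------------
    # Engine / protocol defaults.
    "engine": {
        "dt": 0.01,                    # ms, fixed-step RK4
        "spike_threshold": -10.0,      # mV upward crossing defines a spike
        "spike_lockout": 1.0,          # ms refractory lockout per detector
        "divergence_mv": 200.0,        # |Vm| beyond this aborts the run
        # Event-relay delay of the synapse-bearing twin collateral used in
        # antidromic-only mode (measured single-cell collateral transit).
        "collateral_relay_delay": 1.0,  # ms
    },
    "protocol": {
        "duration": 5000.0,    # ms
        "dbs_onset": 2000.0,   # ms
        "dbs_duration": 1000.0,  # ms
        "n_repeats": 5,
    },
    # ------------------------------------------------------------------
    # Analysis defaults.
    "analysis": {
        "beta_lo": 13.0, "beta_hi": 30.0,      # Hz
        "stim_band_halfwidth": 2.0,            # Hz about the DBS frequency
        "antidromic_window": 10.0,             # ms after pulse onset;
        # covers the measured 4-9 ms conduction + somatic ignition
        # latency; attribution of spikes to pulses is unique, so the
        # window may exceed the interstimulus interval
        "psd_fs": 1000.0,                      # Hz after decimation
        "welch_segment_s": 1.0,
        "welch_overlap": 0.5,
    },
}


# ----------------------------------------------------------------------
# Config file handling


def merge_params(base: dict, override: dict | None) -> dict:
    """Deep-merge ``override`` into a copy of ``base`` and return it."""
    out = copy.deepcopy(base)
    if override:
        _merge_into(out, override)
    return out


def _merge_into(dst: dict, src: dict) -> None:
    for key, val in src.items():
        if isinstance(val, dict) and isinstance(dst.get(key), dict):
            _merge_into(dst[key], val)
        else:
            dst[key] = copy.deepcopy(val)


def load_params(path: str | Path | None = None) -> dict:
    """Load a YAML or JSON config file merged over the defaults."""
    params = default_params()
    if path is None:
        return params
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        override = json.loads(text)
    else:
        override = yaml.safe_load(text)
    if override is not None and not isinstance(override, dict):
        raise TypeError(f"config file {path} must contain a mapping")
    return merge_params(params, override)


def save_params(params: dict, path: str | Path) -> None:
    """Write a parameter tree as YAML (or JSON if the suffix says so)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(params, indent=2))
    else:
        path.write_text(yaml.safe_dump(params, sort_keys=False))


def density_ms_cm2(ps_um2: float) -> float:
    """Convert a channel density from pS/um^2 to mS/cm^2 (exact)."""
    return ps_um2 * PS_PER_UM2_TO_MS_PER_CM2
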
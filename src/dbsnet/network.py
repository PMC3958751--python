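"""Network construction: populations, geometry and synaptic connectivity.

Populations (default 100 neurons each): cortical pyramidal neurons,
cortical interneurons, STN and GPe.  Directed pathways:

========================  =============================================
cortex -> STN             each axon collateral excites its 10 nearest
                          STN neurons (Euclidean distance from the
                          collateral terminal), giving a mean STN
                          in-degree of ~10
GPe -> STN                each STN neuron is inhibited by its single
                          nearest GPe neuron
STN -> GPe                each STN neuron excites its 2 closest GPe
                          neurons
GPe -> GPe                each GPe neuron is inhibited by its 2 closest
                          GPe neighbours (self-inhibition)
cortex -> interneuron     all-to-all
interneuron -> cortex     all-to-all
========================  =============================================

Synaptic currents use alpha-function conductances
``s(t) = ((t - t0)/tau) exp(1 - (t - t0)/tau)`` (peak 1 at t - t0 = tau)
with per-pathway rise times, gains and reversal potentials.

Collateral geometry: the axon collaterals run mutually parallel to the
z axis through the STN volume, their centers drawn uniformly in an
annulus around the point electrode in the x-y plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import default_params

__all__ = ["Synapse", "NetworkGraph", "NoiseSpec", "build_network",
           "alpha_synapse_value", "synaptic_current", "pathway_tau",
           "PATHWAYS"]

#: Pathway -> alpha-function rise time (ms).
_PATHWAY_TAU = {
    "cortex->stn": 0.8,
    "gpe->stn": 0.8,
    "gpe->gpe": 0.86,
    "stn->gpe": 0.2,
    "cortex->interneuron": 0.5,
    "interneuron->cortex": 0.93,
}

PATHWAYS = tuple(_PATHWAY_TAU)


def pathway_tau(pathway: str) -> float:
    """Rise time (ms) of the alpha-function conductance of a pathway."""
    try:
        return _PATHWAY_TAU[pathway]
    except KeyError:
        raise KeyError(
            f"unknown pathway {pathway!r}; known: {sorted(_PATHWAY_TAU)}"
        ) from None


def alpha_synapse_value(t, t0, tau: float):
    """Dimensionless alpha-function conductance factor.

    ``s = ((t - t0)/tau) exp(1 - (t - t0)/tau)`` for t >= t0, else 0;
    zero at onset, peak value exactly 1 at ``t - t0 = tau``, monotone
    decay afterwards.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = (np.asarray(t, dtype=float) - t0) / tau
    s = np.where(x >= 0.0, x * np.exp(1.0 - x), 0.0)
    return float(s) if s.ndim == 0 else s


@dataclass
class Synapse:
    """One directed synaptic connection with its active event list."""
    pre: int
    post: int
    pathway: str
    gain: float                    # mS/cm^2 of postsynaptic membrane
    e_rev: float                   # mV
    tau: float                     # ms rise time
    events: list = field(default_factory=list)   # spike onset times t0 (ms)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")

    def add_event(self, t0: float) -> None:
        self.events.append(float(t0))

    def prune(self, t: float, cutoff_taus: float = 10.0) -> None:
        """Drop events older than ``cutoff_taus`` rise times."""
        horizon = t - cutoff_taus * self.tau
        self.events = [t0 for t0 in self.events if t0 >= horizon]

    def conductance_factor(self, t: float) -> float:
        return float(sum(alpha_synapse_value(t, t0, self.tau)
                         for t0 in self.events))


def synaptic_current(vm_post: float, synapses: list[Synapse], t: float
                     ) -> float:
    """Total synaptic current (uA/cm^2, outward positive) onto a neuron.

    ``I = sum_k g_k (V_post - E_rev,k) sum_j s_j(t)``; the membrane
    equation subtracts this term, so an excitatory event (E_rev above
    Vm) depolarizes and an inhibitory one hyperpolarizes.
    """
    total = 0.0
    for syn in synapses:
        total += syn.gain * (vm_post - syn.e_rev) * syn.conductance_factor(t)
    return total


@dataclass
class NoiseSpec:
    """Additive membrane-current noise: Gaussian, mean 0, per-neuron
    independent streams reproducible from the seed."""
    sigma: float = 0.001     # uA/cm^2
    mean: float = 0.0
    seed: int = 0

    def stream(self, neuron_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(neuron_index,)))


@dataclass
class NetworkGraph:
    """Populations, positions and directed edge lists of the network."""
    populations: dict
    edges: dict                      # pathway -> (pre ids, post ids)
    stn_pos: np.ndarray              # (n_stn, 3) um
    gpe_pos: np.ndarray              # (n_gpe, 3) um
    collateral_xy: np.ndarray        # (n_cortical, 2) um, cloud centers
    collateral_z0: np.ndarray        # (n_cortical,) axial center offsets
    collateral_terminals: np.ndarray  # (n_cortical, 3) um
    seed: int = 0

    def in_degree(self, pathway: str) -> np.ndarray:
        pre, post = self.edges[pathway]
        n_post = self.populations[pathway.split("->")[1]]
        return np.bincount(post, minlength=n_post)

    def out_degree(self, pathway: str) -> np.ndarray:
        pre, post = self.edges[pathway]
        n_pre = self.populations[pathway.split("->")[0]]
        return np.bincount(pre, minlength=n_pre)

    # -- serialization -------------------------------------------------

    def to_csv(self, directory: str | Path, params: dict | None = None
               ) -> None:
        """Write edge list, positions and a JSON provenance block."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        p = params or default_params()
        rows = []
        for pathway, (pre, post) in self.edges.items():
            gain = p["synapses"][pathway]["gain"]
            tau = p["synapses"][pathway]["tau"]
            for a, b in zip(pre, post):
                rows.append((int(a), int(b), pathway, gain, tau))
        pd.DataFrame(rows, columns=["pre_id", "post_id", "pathway", "gain",
                                    "tau"]).to_csv(d / "edges.csv",
                                                   index=False)
        pos_rows = []
        for name, arr in (("stn", self.stn_pos), ("gpe", self.gpe_pos),
                          ("collateral_terminal", self.collateral_terminals)):
            for i, xyz in enumerate(arr):
                pos_rows.append((name, i, *xyz))
        pd.DataFrame(pos_rows, columns=["population", "id", "x", "y", "z"]
                     ).to_csv(d / "positions.csv", index=False)
        (d / "provenance.json").write_text(json.dumps(
            {"seed": int(self.seed), "populations": self.populations},
            indent=2))

    @classmethod
    def from_csv(cls, directory: str | Path) -> "NetworkGraph":
        d = Path(directory)
        edges_df = pd.read_csv(d / "edges.csv")
        pos_df = pd.read_csv(d / "positions.csv")
        prov = json.loads((d / "provenance.json").read_text())
        edges = {}
        for pathway, grp in edges_df.groupby("pathway"):
            edges[pathway] = (grp["pre_id"].to_numpy(),
                              grp["post_id"].to_numpy())

        def pos(name):
            grp = pos_df[pos_df["population"] == name].sort_values("id")
            return grp[["x", "y", "z"]].to_numpy()

        term = pos("collateral_terminal")
        return cls(populations=prov["populations"], edges=edges,
                   stn_pos=pos("stn"), gpe_pos=pos("gpe"),
                   collateral_xy=term[:, :2],
                   collateral_z0=term[:, 2] - term[:, 2].mean(),
                   collateral_terminals=term, seed=prov["seed"])


def _nearest(src_pos: np.ndarray, dst_pos: np.ndarray, k: int,
             exclude_self: bool = False) -> np.ndarray:
    """Indices (n_src, k) of the k nearest dst points for each src point."""
    d2 = ((src_pos[:, None, :] - dst_pos[None, :, :]) ** 2).sum(axis=-1)
    if exclude_self:
        np.fill_diagonal(d2, np.inf)
    return np.argsort(d2, axis=1)[:, :k]


def build_network(params: dict | None = None, seed: int = 0) -> NetworkGraph:
    """Construct the network graph: positions and all pathway edge lists.

    Deterministic for a given seed.  Raises if a population is too small
    for its nearest-neighbour rule.
    """
    p = params or default_params()
    net = p["network"]
    n_cx = int(net["n_cortical"])
    n_in = int(net["n_interneuron"])
    n_stn = int(net["n_stn"])
    n_gpe = int(net["n_gpe"])
    if min(n_cx, n_in, n_stn, n_gpe) < 3:
        raise ValueError("populations must have at least 3 neurons for the "
                         "nearest-neighbour connectivity rules")
    if n_stn < net["n_stn_per_collateral"]:
        raise ValueError("STN population smaller than the per-collateral "
                         "target count")
    rng = np.random.default_rng(seed)

    # Collateral cloud: centers in an annulus around the electrode,
    # collaterals parallel to z.
    r = np.sqrt(rng.uniform(net["collateral_r_min"] ** 2,
                            net["collateral_r_max"] ** 2, n_cx))
    phi = rng.uniform(0.0, 2.0 * np.pi, n_cx)
    coll_xy = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    geom = p["geometry"]
    half_l = geom["collateral_l"] / 2.0
    zj = net.get("collateral_z_jitter", 0.0)
    coll_z0 = rng.uniform(-zj, zj, n_cx)
    terminals = np.column_stack([coll_xy, coll_z0 + half_l])

    def _box_points(box, n):
        return np.column_stack([rng.uniform(box[0], box[1], n),
                                rng.uniform(box[2], box[3], n),
                                rng.uniform(box[4], box[5], n)])

    stn_pos = _box_points(net["stn_box"], n_stn)
    gpe_pos = _box_points(net["gpe_box"], n_gpe)

    edges = {}
    # cortex -> STN: each collateral to its k nearest STN neurons
    k = int(net["n_stn_per_collateral"])
    idx = _nearest(terminals, stn_pos, k)
    edges["cortex->stn"] = (np.repeat(np.arange(n_cx), k), idx.ravel())
    # GPe -> STN: nearest GPe inhibits each STN neuron
    k = int(net["n_gpe_to_stn"])
    idx = _nearest(stn_pos, gpe_pos, k)
    edges["gpe->stn"] = (idx.ravel(), np.repeat(np.arange(n_stn), k))
    # STN -> GPe: each STN excites its closest GPe neurons
    k = int(net["n_stn_to_gpe"])
    idx = _nearest(stn_pos, gpe_pos, k)
    edges["stn->gpe"] = (np.repeat(np.arange(n_stn), k), idx.ravel())
    # GPe -> GPe: self-inhibition from the closest neighbours
    k = int(net["n_gpe_to_gpe"])
    idx = _nearest(gpe_pos, gpe_pos, k, exclude_self=True)
    edges["gpe->gpe"] = (idx.ravel(), np.repeat(np.arange(n_gpe), k))
    # cortex <-> interneuron: all-to-all in both directions
    edges["cortex->interneuron"] = (
        np.repeat(np.arange(n_cx), n_in),
        np.tile(np.arange(n_in), n_cx))
    edges["interneuron->cortex"] = (
        np.repeat(np.arange(n_in), n_cx),
        np.tile(np.arange(n_cx), n_in))

    return NetworkGraph(
        populations={"cortex": n_cx, "interneuron": n_in, "stn": n_stn,
                     "gpe": n_gpe},
        edges=edges, stn_pos=stn_pos, gpe_pos=gpe_pos,
        collateral_xy=coll_xy, collateral_z0=coll_z0,
        collateral_terminals=terminals, seed=seed)
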
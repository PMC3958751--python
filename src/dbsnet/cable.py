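"""Multicompartment cortical-neuron morphology.

Compartment chain: soma -> AIS -> (node, internode) x 10 -> collateral
(attached to the last node).  The unmyelinated collateral is split into
several equal compartments so the extracellular field can couple along
it; the main axon uses one compartment per node and per internode.

Myelin is represented in the reduced single-cable way: internodal
specific capacitance and membrane conductances are divided by a wrap
factor, which preserves the published per-membrane channel densities
while giving realistic internodal charging times.

Axial coupling between adjacent compartments uses the series resistance
of the two half-compartments; the collateral branch point (last node)
has three neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import default_params

__all__ = ["CableMorphology", "build_cable", "KIND_SOMA", "KIND_AIS",
           "KIND_NODE", "KIND_INTERNODE", "KIND_COLLATERAL"]

KIND_SOMA, KIND_AIS, KIND_NODE, KIND_INTERNODE, KIND_COLLATERAL = range(5)
_KIND_NAMES = ("soma", "ais", "node", "internode", "collateral")


@dataclass
class CableMorphology:
    """Compartmentalized cortical neuron (geometry units: um, cm^2, mS)."""
    kinds: np.ndarray          # int8[C], compartment kind codes
    lengths: np.ndarray        # um
    diams: np.ndarray          # um
    areas: np.ndarray          # cm^2 lateral membrane area
    cm: np.ndarray             # uF/cm^2 effective (myelin-scaled)
    g_na: np.ndarray           # mS/cm^2 effective
    g_k: np.ndarray
    g_kd: np.ndarray
    g_leak: np.ndarray
    e_leak: np.ndarray         # mV per compartment
    edges: np.ndarray          # int64[E, 2] adjacent compartment pairs
    g_edge: np.ndarray         # mS absolute axial conductance per edge
    junction_edge: int         # index of the last-node <-> collateral edge
    soma_idx: int
    ais_idx: int
    node_idx: np.ndarray       # indices of the 10 nodes
    collateral_idx: np.ndarray  # indices of the collateral compartments
    arc_z: np.ndarray          # axial position of collateral comps along z (um)

    @property
    def n_comp(self) -> int:
        return len(self.kinds)

    @property
    def terminal_idx(self) -> int:
        return int(self.collateral_idx[-1])

    def kind_name(self, c: int) -> str:
        return _KIND_NAMES[self.kinds[c]]


def _half_resistance_kohm(ri_ohm_cm: float, length_um: float, diam_um: float
                          ) -> float:
    """Axial resistance (kOhm) of half a cylindrical compartment."""
    l_cm = length_um * 1e-4 / 2.0
    a_cm2 = np.pi * (diam_um * 1e-4) ** 2 / 4.0
    return ri_ohm_cm * l_cm / a_cm2 * 1e-3


def build_cable(params: dict | None = None) -> CableMorphology:
    """Build the default cortical-neuron cable from a parameter tree."""
    p = params or default_params()
    g = p["geometry"]
    ax = p["axon"]
    n_nodes = int(g["n_nodes"])
    ncol = int(g["n_collateral_comps"])

    kinds = [KIND_SOMA, KIND_AIS]
    lengths = [g["soma_l"], g["ais_l"]]
    diams = [g["soma_d"], g["ais_d"]]
    for _ in range(n_nodes):
        kinds += [KIND_NODE, KIND_INTERNODE]
        lengths += [g["node_l"], g["internode_l"]]
        diams += [g["node_d"], g["internode_d"]]
    col_l = g["collateral_l"] / ncol
    for _ in range(ncol):
        kinds.append(KIND_COLLATERAL)
        lengths.append(col_l)
        diams.append(g["collateral_d"])
    kinds = np.array(kinds, dtype=np.int8)
    lengths = np.array(lengths, dtype=float)
    diams = np.array(diams, dtype=float)
    areas = np.pi * diams * lengths * 1e-8          # um^2 -> cm^2
    C = len(kinds)
    last_node = 2 + 2 * (n_nodes - 1)               # index of node 10
    first_col = 2 + 2 * n_nodes

    # Effective membrane parameters (pS/um^2 -> mS/cm^2 is a factor 0.1)
    name_of = {KIND_AIS: "ais", KIND_NODE: "node",
               KIND_INTERNODE: "internode", KIND_COLLATERAL: "collateral"}
    cm = np.full(C, ax["cm"])
    g_na = np.zeros(C)
    g_k = np.zeros(C)
    g_kd = np.zeros(C)
    g_leak = np.full(C, 0.1 * ax["g_leak_ps_um2"])
    e_leak = np.full(C, ax["e_leak"])
    soma = p["soma"]
    cm[0] = soma["cm"]
    g_na[0] = soma["g_na"]
    g_k[0] = soma["g_kd"]       # soma delayed rectifier
    g_kd[0] = soma["g_m"]       # soma slot reused for the adaptation current
    g_leak[0] = soma["g_leak"]
    e_leak[0] = soma["e_leak"]
    for c in range(1, C):
        nm = name_of[kinds[c]]
        g_na[c] = 0.1 * ax["g_na_ps_um2"][nm]
        g_k[c] = 0.1 * ax["g_k_ps_um2"][nm]
        g_kd[c] = 0.1 * ax["g_kd_ps_um2"][nm]
    # Myelin: wraps shield the internodal capacitance and the voltage-
    # gated channels, but the sheath still passes DC leak, so g_leak is
    # left unscaled (this is what repolarizes the internode).
    myelin = float(ax["myelin_factor"])
    inter = kinds == KIND_INTERNODE
    for arr in (cm, g_na, g_k, g_kd):
        arr[inter] /= myelin

    # Edges: chain soma..last internode, then branch last node -> collateral
    edges = [(i, i + 1) for i in range(first_col - 1)]
    edges.append((last_node, first_col))
    junction_edge = len(edges) - 1
    for j in range(ncol - 1):
        edges.append((first_col + j, first_col + j + 1))
    edges = np.array(edges, dtype=np.int64)
    ri = ax["ri_ohm_cm"]
    rhalf = np.array([_half_resistance_kohm(ri, lengths[c], diams[c])
                      for c in range(C)])
    g_edge = 1.0 / (rhalf[edges[:, 0]] + rhalf[edges[:, 1]])   # mS

    arc_z = (np.arange(ncol) + 0.5) * col_l - g["collateral_l"] / 2.0
    return CableMorphology(
        kinds=kinds, lengths=lengths, diams=diams, areas=areas, cm=cm,
        g_na=g_na, g_k=g_k, g_kd=g_kd, g_leak=g_leak, e_leak=e_leak,
        edges=edges, g_edge=g_edge, junction_edge=junction_edge,
        soma_idx=0, ais_idx=1,
        node_idx=np.array([2 + 2 * k for k in range(n_nodes)]),
        collateral_idx=np.arange(first_col, first_col + ncol),
        arc_z=arc_z)
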
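"""Arterial/venous blood network: advection, flows and vessel balances.

Blood leaves the heart (the chest segment) through a directed tree of
arterial nodes, is consumed locally by core perfusion and skin perfusion,
and returns through the mirror tree of venous nodes.  Venous blood re-enters
the chest arterial node through the heart without heat exchange, closing the
loop so that advection is exactly energy-conserving for any temperature
state.

Per segment, the vessels exchange heat with the core through lumped
convective conductances ``h_a``, ``h_v`` (the products Σh·A of the vessel
surface).  Their values derive from circulatory vessel geometry that is not
part of this model's data; they are exposed as configuration with defaults
proportional to the vessel heat capacitance (``h = κ C_bl``, κ = 0.01 W/K
per J/K), a calibration documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_parameters import SegmentParameters

__all__ = ["BloodNetwork", "build_default_network", "update_flows", "vessel_rhs"]

#: Default ratio of core–vessel conductance to vessel capacitance, W/K per J/K.
KAPPA_H = 0.01

#: Default anatomical chains (child ← parent), chest is the heart/root.
_DEFAULT_PARENTS = {
    "chest": "chest",
    "head": "chest",
    "abdomen": "chest",
    "left_upper_arm": "chest",
    "right_upper_arm": "chest",
    "left_forearm": "left_upper_arm",
    "right_forearm": "right_upper_arm",
    "left_hand": "left_forearm",
    "right_hand": "right_forearm",
    "left_thigh": "abdomen",
    "right_thigh": "abdomen",
    "left_calf": "left_thigh",
    "right_calf": "right_thigh",
    "left_foot": "left_calf",
    "right_foot": "right_calf",
}


@dataclass
class BloodNetwork:
    """Directed vessel tree rooted at the heart segment.

    ``parent[j]`` is the upstream segment index (the root points at itself).
    ``h_a``/``h_v`` are the core–vessel convective conductances, W/K.
    Mass flows are filled in by :func:`update_flows`.
    """

    parent: np.ndarray                 # (n,) int
    root: int
    h_a: np.ndarray                    # (n,) W/K
    h_v: np.ndarray                    # (n,) W/K
    order: np.ndarray = field(init=False)   # leaf→root accumulation order

    def __post_init__(self) -> None:
        n = len(self.parent)
        if self.parent[self.root] != self.root:
            raise ValueError("root must be its own parent")
        # depth-sort: deepest segments first so children accumulate before parents
        depth = np.zeros(n, dtype=int)
        for j in range(n):
            k, d = j, 0
            seen = 0
            while k != self.root:
                k = int(self.parent[k])
                d += 1
                seen += 1
                if seen > n:
                    raise ValueError(f"segment {j} is not connected to the root")
            depth[j] = d
        self.order = np.argsort(-depth, kind="stable")

    @property
    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self.parent))]
        for j, p in enumerate(self.parent):
            if j != self.root:
                out[int(p)].append(j)
        return out


def build_default_network(segments: list[SegmentParameters],
                          h_a: dict[str, float] | None = None,
                          h_v: dict[str, float] | None = None) -> BloodNetwork:
    """Build the anatomical vessel tree for the named segments.

    ``h_a``/``h_v`` overrides are keyed by segment name; defaults are
    ``κ·C_bl`` per vessel.
    """
    names = [s.name for s in segments]
    idx = {n: i for i, n in enumerate(names)}
    parent = np.array([idx[_DEFAULT_PARENTS[n]] for n in names], dtype=int)
    ha = np.array([(h_a or {}).get(s.name, KAPPA_H * s.C_bl_a) for s in segments])
    hv = np.array([(h_v or {}).get(s.name, KAPPA_H * s.C_bl_v) for s in segments])
    return BloodNetwork(parent=parent, root=idx["chest"], h_a=ha, h_v=hv)


def update_flows(network: BloodNetwork,
                 local_demand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate segment flow demands leaf-to-root into branch flows.

    ``local_demand[j]`` is the blood consumed inside segment ``j`` (core
    perfusion + skin perfusion), kg/s.  Returns ``(m_a, m_v)``: the arterial
    and venous mass flow through each segment's vessels; conservation holds
    at every branch point and the venous tree mirrors the arterial one.
    """
    demand = np.asarray(local_demand, dtype=float)
    if np.any(demand < 0.0):
        raise ValueError("negative blood flow demand")
    m_a = demand.copy()
    for j in network.order:
        j = int(j)
        if j != network.root:
            m_a[int(network.parent[j])] += m_a[j]
    return m_a, m_a.copy()


def vessel_rhs(T_cr: float, T_bl_a: float, T_bl_v: float,
               T_a_upstream: float, venous_inflows: list[tuple[float, float]],
               m_a: float, m_return: float,
               h_a: float, h_v: float, c_bl: float,
               C_bl_a: float, C_bl_v: float) -> tuple[float, float]:
    """Energy balance of one segment's artery and vein nodes, K/s.

    Artery: core–vessel convection plus upstream advection at the full
    branch flow (at the root the upstream blood is the heart return, i.e.
    the root vein).  Vein: core–vessel convection, the local perfusion
    return ``m_return`` (the full stream consumed by the segment, leaving
    the core at ``T_cr``), and the advective distal venous returns supplied
    as ``(mass_flow, temperature)`` pairs.
    """
    dTa = (h_a * (T_cr - T_bl_a) + m_a * c_bl * (T_a_upstream - T_bl_a)) / C_bl_a
    q = h_v * (T_cr - T_bl_v) + m_return * c_bl * (T_cr - T_bl_v)
    for m, T in venous_inflows:
        q += m * c_bl * (T - T_bl_v)
    return dTa, q / C_bl_v
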
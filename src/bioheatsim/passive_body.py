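"""The 105-node passive system: state vector and energy-balance RHS.

Node layout per segment: one core, one arterial and one venous blood node,
and four angular skin sectors.  The state vector stacks, in canonical
segment order::

    [T_cr (n) | T_bl_a (n) | T_bl_v (n) | T_sk (n×4, row-major) | sweat_kg]

All temperatures are °C; the single auxiliary entry is the cumulative sweat
mass (kg), from which dehydration ``D`` and the heart-rate increment derive.

Sign convention: every internal heat flow is defined as heat leaving the
core (core→skin conduction and perfusion, core→vessel convection, core→vein
perfusion return), subtracted in the core balance and added in the receiving
node, so all internal exchanges are exactly antisymmetric and the adiabatic
body conserves total enthalpy Σ C·T to round-off under any Runge–Kutta
scheme (the invariant is linear in the state).

The perfusion stream through a segment uses the total locally consumed flow
(core perfusion plus skin perfusion): it equilibrates in the core, the skin
loop exchanges pairwise with the core (``ṁ_sk c_bl (T_cr − T_sk)``, counted
once in each balance), and the full stream returns to the local vein at
core temperature.  This routing keeps the printed structure of the core
balance — both the artery→core and the core→skin perfusion terms — while
closing the advective loop exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_parameters import SegmentParameters, ThermoregParams
from .circulation import BloodNetwork, build_default_network, update_flows
from .environment_exchange import (LAMBDA_SWEAT, ClothingSpec,
                                   ResolvedEnvironment,
                                   saturation_vapor_pressure,
                                   wettedness_from_demand)
from .thermoregulation import ControlOutputs, compute_controls

__all__ = [
    "BodyState",
    "BodyModel",
    "HeatFlows",
    "respiratory_heat_loss",
    "perfusion_redistribution",
    "core_rhs",
    "skin_sector_rhs",
    "assemble_rhs",
    "surface_fluxes",
    "compute_heat_flows",
]


def respiratory_heat_loss(M_cr_chest: float, T_air: float, P_air: float) -> float:
    """Respiratory heat loss of the chest core, W.

    ``RES = 0.0014 M_cr (34 − T_air) + 0.0173 M_cr (5.87 − P_air)`` with
    ``T_air`` in °C and ``P_air`` in kPa.  Negative in hot, humid air (a
    physical heat gain through breathing).
    """
    return 0.0014 * M_cr_chest * (34.0 - T_air) + 0.0173 * M_cr_chest * (5.87 - P_air)


def perfusion_redistribution(T_sk, m_sk_perfusion: float) -> np.ndarray:
    """Split a segment's skin perfusion over its four sectors.

    Hotter sectors receive more flow: ``ṁ_i = (ṁ/4)(1 + δ_i/Σmax(0,δ_i))``
    with ``δ_i`` the sector's deviation from the segment skin mean.  With
    isothermal sectors the flow splits equally; any negative share is
    clipped to zero with the deficit removed proportionally from the
    positive sectors, so the total is conserved exactly.
    """
    if m_sk_perfusion < 0.0:
        raise ValueError("m_sk_perfusion must be ≥ 0")
    T = np.asarray(T_sk, dtype=float)
    delta = T - T.mean()
    pos = np.sum(np.maximum(delta, 0.0))
    quarter = m_sk_perfusion / 4.0
    if pos <= 0.0:
        return np.full(4, quarter)
    m = quarter * (1.0 + delta / pos)
    neg = -np.sum(np.minimum(m, 0.0))
    if neg > 0.0:
        m = np.maximum(m, 0.0)
        s = m.sum()
        if s > 0.0:
            m *= m_sk_perfusion / s
    return m


def _redistribute_all(T_sk: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Vectorized :func:`perfusion_redistribution` over all segments."""
    delta = T_sk - T_sk.mean(axis=1, keepdims=True)
    pos = np.maximum(delta, 0.0).sum(axis=1, keepdims=True)
    quarter = totals[:, None] / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mod = np.where(pos > 0.0, delta / np.where(pos > 0.0, pos, 1.0), 0.0)
    m = quarter * (1.0 + mod)
    negsum = np.minimum(m, 0.0).sum(axis=1)
    if np.any(negsum < 0.0):
        m = np.maximum(m, 0.0)
        s = m.sum(axis=1, keepdims=True)
        scale = np.where(s > 0.0, totals[:, None] / np.where(s > 0.0, s, 1.0), 1.0)
        m = m * scale
    return m


@dataclass
class BodyState:
    """Structured view of the simulator state at one instant."""

    T_cr: np.ndarray              # (n,) core temperatures, °C
    T_bl_a: np.ndarray            # (n,) arterial blood, °C
    T_bl_v: np.ndarray            # (n,) venous blood, °C
    T_sk: np.ndarray              # (n, 4) sector skin temperatures, °C
    sweat_cumulative: float = 0.0  # kg
    t: float = 0.0                 # s

    @property
    def n_segments(self) -> int:
        return len(self.T_cr)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.T_cr, self.T_bl_a, self.T_bl_v, self.T_sk.ravel(),
            [self.sweat_cumulative]])

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int, t: float = 0.0) -> "BodyState":
        y = np.asarray(y, dtype=float)
        return cls(T_cr=y[0:n].copy(), T_bl_a=y[n:2 * n].copy(),
                   T_bl_v=y[2 * n:3 * n].copy(),
                   T_sk=y[3 * n:7 * n].reshape(n, 4).copy(),
                   sweat_cumulative=float(y[7 * n]), t=t)

    def check(self) -> None:
        """Sanity invariants: finite temperatures within [0, 60] °C, D ≥ 0."""
        temps = np.concatenate([self.T_cr, self.T_bl_a, self.T_bl_v,
                                self.T_sk.ravel()])
        if not np.all(np.isfinite(temps)):
            bad = int(np.argmax(~np.isfinite(temps)))
            raise FloatingPointError(
                f"non-finite temperature at node index {bad} (t={self.t:.1f} s)")
        if temps.min() < 0.0 or temps.max() > 60.0:
            bad = int(np.argmax((temps < 0.0) | (temps > 60.0)))
            raise ValueError(
                f"temperature {temps[bad]:.2f} °C outside the [0, 60] °C "
                f"sanity band at node index {bad} (t={self.t:.1f} s)")
        if self.sweat_cumulative < -1e-12:
            raise ValueError("cumulative sweat mass went negative")


@dataclass
class HeatFlows:
    """Diagnostic snapshot of every heat flow, W (per segment / sector)."""

    Q_cr_sk: np.ndarray         # (n, 4) core→skin conduction
    Q_perf_cr_sk: np.ndarray    # (n, 4) core→skin perfusion
    Q_perf_a_cr: np.ndarray     # (n,) core→artery perfusion exchange
    Q_cr_a: np.ndarray          # (n,) core→artery convection
    Q_cr_v: np.ndarray          # (n,) core→vein convection
    Q_perf_cr_v: np.ndarray     # (n,) core→vein perfusion return
    Q_adj_a: np.ndarray         # (n,) arterial advection gain
    Q_adj_v: np.ndarray         # (n,) venous advection gain (all inflows)
    RES: np.ndarray             # (n,) respiratory loss (chest only)
    CON: np.ndarray             # (n, 4)
    EVA: np.ndarray             # (n, 4)
    RAD: np.ndarray             # (n, 4) total radiation (MRT part + panels)
    angular: np.ndarray         # (n, 4) angular skin conduction gain


class BodyModel:
    """A body compiled to flat arrays, ready for time integration.

    Parameters
    ----------
    segments, thermo
        Output of :func:`bioheatsim.body_parameters.load_default_body`
        (possibly overridden).
    network
        Blood network; defaults to the anatomical tree for the 15-segment
        body (the chest is the heart/root).
    clothing
        Per-segment clothing resistances; defaults to a bare body.
    """

    def __init__(self, segments: list[SegmentParameters],
                 thermo: ThermoregParams,
                 network: BloodNetwork | None = None,
                 clothing: ClothingSpec | None = None):
        self.segments = list(segments)
        self.thermo = thermo
        self.names = [s.name for s in self.segments]
        self.n = len(self.segments)
        self.network = network if network is not None else \
            build_default_network(self.segments)
        self.clothing = clothing or ClothingSpec()

        get = lambda f: np.array([getattr(s, f) for s in self.segments])
        self.A = get("A")
        self.A_sector = self.A / 4.0
        self.M_cr = get("M_cr")
        self.M_sk_sector = get("M_sk")[:, None] / 4.0 * np.ones((1, 4))
        self.W_cr = get("W_cr")
        self.C_cr = get("C_cr")
        self.C_a = get("C_bl_a")
        self.C_v = get("C_bl_v")
        self.C_sk_sector = get("C_sk")[:, None] / 4.0 * np.ones((1, 4))
        self.K_sector = get("K_cr_sk") / 4.0
        self.m_basal = get("m_sk_basal")
        self.epsilon = get("epsilon")
        # angular conduction coefficient of Eq-form K_sk·L_n·th_sk/r² per Δθ²
        dtheta = np.pi / 2.0
        self.k_ang = (get("K_sk") * get("L_n") * get("th_sk")
                      / get("r") ** 2 / dtheta ** 2)
        #: cm³/h → kg/s at blood density
        self.flow_to_kgps = 1e-6 * thermo.blood_density / 3600.0
        # core perfusion demand ∝ basal core metabolic rate
        m_tot = self.M_cr.sum()
        self.core_flow_cm3h = (thermo.core_perfusion_total * self.M_cr / m_tot
                               if m_tot > 0 else np.zeros(self.n))
        self.head_index = self.names.index("head") if "head" in self.names \
            else self.network.root
        self.chest_index = self.network.root
        # per-node heat capacity vector aligned with the state layout
        self.C_nodes = np.concatenate([
            self.C_cr, self.C_a, self.C_v, self.C_sk_sector.ravel()])

    # -- controller ------------------------------------------------------
    def controls(self, y: np.ndarray, env: ResolvedEnvironment,
                 metabolism_enabled: bool = True) -> ControlOutputs:
        n = self.n
        return compute_controls(
            T_cr=y[0:n], T_sk=y[3 * n:7 * n].reshape(n, 4),
            sweat_cumulative=float(y[7 * n]),
            T_air_mean=env.T_air_mean, thermo=self.thermo,
            segments=self.segments, head_index=self.head_index,
            metabolism_enabled=metabolism_enabled)

    def clothing_factors(self, h_c: float, h_r: float,
                         h_e: float) -> tuple[np.ndarray, np.ndarray]:
        i_cl = np.array([self.clothing.i_cl.get(nm, 0.0) for nm in self.names])
        r_ecl = np.array([self.clothing.r_ecl.get(nm, 0.0) for nm in self.names])
        return (1.0 / (1.0 + (h_c + h_r) * i_cl),
                1.0 / (1.0 + h_e * r_ecl))


def surface_fluxes(model: BodyModel, T_sk: np.ndarray,
                   env: ResolvedEnvironment, controls: ControlOutputs
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sector CON, EVA, RAD (n×4 each, W; positive = loss)."""
    n4 = np.ones_like(T_sk)
    A = model.A_sector[:, None] * n4
    CON = A * env.h_c * (T_sk - env.T_air) * env.f_dry[:, None]

    RAD = A * env.h_r * (T_sk - env.T_mrt) * (1.0 - env.panel_F_total)
    T4 = (T_sk + 273.15) ** 4
    for coeff, T_r in env.rad2_terms:
        RAD = RAD + A * coeff * (T4 - (T_r + 273.15) ** 4)
    RAD = RAD * env.f_dry[:, None]

    p_sat = saturation_vapor_pressure(T_sk)
    h_e_eff = env.h_e * env.f_evap[:, None]
    capacity = A * h_e_eff * np.maximum(p_sat - env.P_air, 0.0)
    demand_w = controls.sweat_sector_kgh * LAMBDA_SWEAT / 3600.0
    w = wettedness_from_demand(demand_w, capacity)
    EVA = w * capacity
    return CON, EVA, RAD


def core_rhs(M_cr: float, W_cr: float, C_cr: float,
             Q_cr_sk, Q_perf_cr_sk, Q_perf_a_cr: float,
             Q_cr_a: float, Q_cr_v: float, RES: float = 0.0) -> float:
    """Core energy balance, K/s (all flows defined as heat leaving the core).

    ``RES`` is nonzero only for the chest core.
    """
    return ((M_cr - W_cr) - float(np.sum(Q_cr_sk)) - float(np.sum(Q_perf_cr_sk))
            - Q_perf_a_cr - Q_cr_a - Q_cr_v - RES) / C_cr


def skin_sector_rhs(T_sk_ring, sector: int, k_ang: float,
                    M_sk_sector: float, Q_cr_sk: float, Q_perf_cr_sk: float,
                    CON: float, EVA: float, RAD: float,
                    C_sk_sector: float) -> float:
    """One skin sector's energy balance, K/s.

    ``T_sk_ring`` is the segment's 4-sector ring; the angular conduction is
    the periodic central second difference with Δθ = π/2 folded into
    ``k_ang``.
    """
    T = np.asarray(T_sk_ring, dtype=float)
    i = sector
    ang = k_ang * (T[(i + 1) % 4] - 2.0 * T[i] + T[(i - 1) % 4])
    return (ang + M_sk_sector + Q_cr_sk + Q_perf_cr_sk - CON - EVA - RAD) \
        / C_sk_sector


def assemble_rhs(model: BodyModel, y: np.ndarray, env: ResolvedEnvironment,
                 controls: ControlOutputs,
                 metabolism_enabled: bool = True) -> np.ndarray:
    """Full derivative of the state vector (temperatures K/s, sweat kg/s)."""
    n = model.n
    T_cr = y[0:n]
    T_a = y[n:2 * n]
    T_v = y[2 * n:3 * n]
    T_sk = y[3 * n:7 * n].reshape(n, 4)
    c = model.thermo.c_bl

    # blood flows, kg/s
    m_sk_sec = _redistribute_all(T_sk, controls.skin_flow_cm3h) * model.flow_to_kgps
    m_sk_tot = m_sk_sec.sum(axis=1)
    m_cr = model.core_flow_cm3h * model.flow_to_kgps
    m_a, m_v = update_flows(model.network, m_cr + m_sk_tot)

    # boundary exchange
    if env.exchange_enabled:
        CON, EVA, RAD = surface_fluxes(model, T_sk, env, controls)
    else:
        CON = EVA = RAD = np.zeros_like(T_sk)
    RES = np.zeros(n)
    if env.respiration_enabled and env.exchange_enabled:
        j = model.chest_index
        RES[j] = respiratory_heat_loss(
            model.M_cr[j] * controls.metabolic_multiplier,
            float(env.T_air[j].mean()), float(env.P_air[j].mean()))

    # internal flows (heat leaving the core)
    Q_cr_sk = model.K_sector[:, None] * (T_cr[:, None] - T_sk)
    Q_perf_cr_sk = m_sk_sec * c * (T_cr[:, None] - T_sk)
    Q_cr_a = model.network.h_a * (T_cr - T_a)
    Q_cr_v = model.network.h_v * (T_cr - T_v)
    # the full locally consumed stream (core + skin perfusion) equilibrates
    # in the core and returns to the vein at core temperature; the skin loop
    # exchanges pairwise with the core (exactly conservative)
    Q_perf_a_cr = (m_cr + m_sk_tot) * c * (T_cr - T_a)
    Q_perf_cr_v = (m_cr + m_sk_tot) * c * (T_cr - T_v)

    if metabolism_enabled:
        M_core = (model.M_cr * controls.metabolic_multiplier
                  + controls.shiver_w - model.W_cr)
        M_skin = model.M_sk_sector * controls.metabolic_multiplier
    else:
        M_core = np.zeros(n)
        M_skin = np.zeros_like(T_sk)

    dT_cr = (M_core - Q_cr_sk.sum(1) - Q_perf_cr_sk.sum(1)
             - Q_perf_a_cr - Q_cr_a - Q_cr_v - RES) / model.C_cr

    # artery: upstream advection at the full branch flow; the heart feeds
    # the root artery from the root vein (no heat exchange in the heart)
    parent = model.network.parent
    T_up = T_a[parent].copy()
    T_up[model.network.root] = T_v[model.network.root]
    dT_a = (Q_cr_a + m_a * c * (T_up - T_a)) / model.C_a

    # vein: convective + perfusion return (full stream, at T_cr) + children
    q_v = Q_cr_v + Q_perf_cr_v
    child_flux = m_v * c * (T_v - T_v[parent])
    child_flux[model.network.root] = 0.0
    np.add.at(q_v, parent, child_flux)
    dT_v = q_v / model.C_v

    ang = model.k_ang[:, None] * (np.roll(T_sk, 1, axis=1) - 2.0 * T_sk
                                  + np.roll(T_sk, -1, axis=1))
    dT_sk = (ang + M_skin + Q_cr_sk + Q_perf_cr_sk - CON - EVA - RAD) \
        / model.C_sk_sector

    d_sweat = controls.sweat_total_kgh / 3600.0
    dy = np.concatenate([dT_cr, dT_a, dT_v, dT_sk.ravel(), [d_sweat]])
    if not np.all(np.isfinite(dy)):
        bad = int(np.argmax(~np.isfinite(dy)))
        raise FloatingPointError(f"non-finite derivative at state index {bad}")
    return dy


def compute_heat_flows(model: BodyModel, y: np.ndarray,
                       env: ResolvedEnvironment,
                       controls: ControlOutputs) -> HeatFlows:
    """Diagnostic heat-flow snapshot for output/inspection."""
    n = model.n
    T_cr = y[0:n]
    T_a = y[n:2 * n]
    T_v = y[2 * n:3 * n]
    T_sk = y[3 * n:7 * n].reshape(n, 4)
    c = model.thermo.c_bl

    m_sk_sec = _redistribute_all(T_sk, controls.skin_flow_cm3h) * model.flow_to_kgps
    m_sk_tot = m_sk_sec.sum(axis=1)
    m_cr = model.core_flow_cm3h * model.flow_to_kgps
    m_a, m_v = update_flows(model.network, m_cr + m_sk_tot)

    if env.exchange_enabled:
        CON, EVA, RAD = surface_fluxes(model, T_sk, env, controls)
    else:
        CON = EVA = RAD = np.zeros_like(T_sk)
    RES = np.zeros(n)
    if env.respiration_enabled and env.exchange_enabled:
        j = model.chest_index
        RES[j] = respiratory_heat_loss(
            model.M_cr[j] * controls.metabolic_multiplier,
            float(env.T_air[j].mean()), float(env.P_air[j].mean()))

    parent = model.network.parent
    T_up = T_a[parent].copy()
    T_up[model.network.root] = T_v[model.network.root]
    q_v_in = np.zeros(n)
    child_flux = m_v * c * (T_v - T_v[parent])
    child_flux[model.network.root] = 0.0
    np.add.at(q_v_in, parent, child_flux)

    ang = model.k_ang[:, None] * (np.roll(T_sk, 1, axis=1) - 2.0 * T_sk
                                  + np.roll(T_sk, -1, axis=1))
    return HeatFlows(
        Q_cr_sk=model.K_sector[:, None] * (T_cr[:, None] - T_sk),
        Q_perf_cr_sk=m_sk_sec * c * (T_cr[:, None] - T_sk),
        Q_perf_a_cr=(m_cr + m_sk_tot) * c * (T_cr - T_a),
        Q_cr_a=model.network.h_a * (T_cr - T_a),
        Q_cr_v=model.network.h_v * (T_cr - T_v),
        Q_perf_cr_v=(m_cr + m_sk_tot) * c * (T_cr - T_v),
        Q_adj_a=m_a * c * (T_up - T_a),
        Q_adj_v=q_v_in,
        RES=RES, CON=CON, EVA=EVA, RAD=RAD, angular=ang)
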
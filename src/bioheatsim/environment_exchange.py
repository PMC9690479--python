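"""Boundary heat exchange between skin sectors and the environment.

Each skin sector exchanges heat with the surroundings through three channels:

* convection, ``CON = A h_c (T_sk − T_air)``;
* evaporation, ``EVA = w A h_e (P_sat(T_sk) − P_air)`` with the skin
  wettedness ``w`` (fraction of skin behaving as fully wet, ≥ 0.06
  insensible minimum) set by the demanded sweat evaporation;
* radiation split into a linearized exchange with the mean radiant
  temperature, ``A h_r (T_sk − T_mrt)``, plus an explicit Stefan–Boltzmann
  term ``A σ ε F_vf [(T_sk+273.15)⁴ − (T_r+273.15)⁴]`` for each planar
  high-temperature radiant panel, weighted by the purely geometric view
  factor ``F_vf``.

View factors between a skin sector (modelled as a flat vertical strip on the
body surface) and a rectangular panel are computed exactly per surface
element with the contour-integral (Stokes) form of the view-factor integral,
averaged over the sector by midpoint quadrature.  The contour form is
additive over subdivided panels by construction.

Clothing follows a simplified serial-resistance layer: the dry (convective +
radiative) flux is scaled by ``1 / (1 + (h_c+h_r) I_cl)`` and the
evaporative flux by ``1 / (1 + h_e R_e,cl)``; bare segments are unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIGMA_SB",
    "Panel",
    "Stage",
    "EnvironmentSpec",
    "ClothingSpec",
    "ResolvedEnvironment",
    "saturation_vapor_pressure",
    "convective_loss",
    "evaporative_loss",
    "radiative_loss",
    "wettedness_from_demand",
    "apply_clothing",
    "element_view_factor",
    "rect_view_factor",
    "view_factor",
]

SIGMA_SB = 5.670374419e-8  # Stefan–Boltzmann constant, W/(m² K⁴)

#: Latent heat of vaporization of sweat, J/kg.
LAMBDA_SWEAT = 2.426e6

#: Minimum (insensible) skin wettedness.
W_MIN = 0.06


def saturation_vapor_pressure(T: float | np.ndarray) -> float | np.ndarray:
    """Saturation vapor pressure of water over a flat surface, kPa.

    Antoine form fitted for the physiological range (°C in, kPa out);
    ≈ 5.61 kPa at 35 °C.
    """
    p_mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + np.asarray(T, dtype=float)))
    out = 0.133322 * p_mmhg
    return float(out) if np.isscalar(T) else out


# --------------------------------------------------------------------------
# Exchange terms (array-friendly; W, positive = loss from the skin)

def convective_loss(T_sk, T_air, A_sector, h_c):
    """Convective heat loss of a sector, W (negative = gain from hot air)."""
    return A_sector * h_c * (np.asarray(T_sk) - T_air)


def wettedness_from_demand(demand_w, capacity_w):
    """Skin wettedness from demanded sweat evaporation vs. maximal capacity.

    Two-node-model form: ``w = W_MIN + (1 − W_MIN)·demand/capacity`` clipped
    to ``[W_MIN, 1]`` — the skin is never drier than the insensible minimum
    and never more than fully wet.  When the environment allows no
    evaporation (capacity ≤ 0) the skin stays at the insensible minimum.
    """
    demand = np.asarray(demand_w, dtype=float)
    cap = np.asarray(capacity_w, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cap > 0.0, demand / np.where(cap > 0.0, cap, 1.0), 0.0)
    return np.clip(W_MIN + (1.0 - W_MIN) * ratio, W_MIN, 1.0)


def evaporative_loss(T_sk, P_air, wettedness, A_sector, h_e):
    """Evaporative heat loss, W: ``w · A h_e (P_sat(T_sk) − P_air)``, ≥ 0.

    The wettedness scales the full saturation driving potential (the
    fraction of skin behaving as fully wet), so the insensible minimum
    ``w = 0.06`` yields the physiological ~20 W whole-body diffusion loss in
    temperate air.  Floored at zero when the ambient vapor pressure exceeds
    the skin's saturation pressure (no condensation heat gain is modelled).
    """
    w = np.asarray(wettedness, dtype=float)
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("wettedness must lie in [0, 1]")
    p_sat = saturation_vapor_pressure(T_sk)
    return np.maximum(w * A_sector * h_e * (p_sat - np.asarray(P_air)), 0.0)


def radiative_loss(T_sk, T_mrt, panels, A_sector, h_r, epsilon=0.95):
    """Radiative loss, W: linearized MRT part plus explicit panel terms.

    ``panels`` is an iterable of ``(F_vf, T_r)`` pairs already resolved for
    this sector; panels facing other sectors must arrive with ``F_vf = 0``.
    By view-factor additivity the enclosure remainder subtends ``1 − ΣF``,
    so the mean-radiant exchange is weighted by that fraction; without
    panels it reduces to ``A h_r (T_sk − T_mrt)``.
    """
    T_sk = np.asarray(T_sk, dtype=float)
    F_tot = min(1.0, sum(F for F, _ in panels))
    rad = A_sector * h_r * (T_sk - T_mrt) * (1.0 - F_tot)
    for F_vf, T_r in panels:
        rad = rad + A_sector * SIGMA_SB * epsilon * F_vf * (
            (T_sk + 273.15) ** 4 - (T_r + 273.15) ** 4)
    return rad


def apply_clothing(dry_flux, evap_flux, i_cl, r_ecl, h_c, h_r, h_e):
    """Scale raw sector fluxes through a serial clothing resistance.

    The bare-surface dry conductance ``h_c + h_r`` acquires an intrinsic
    insulation ``I_cl`` in series, scaling the dry flux by
    ``1/(1 + (h_c+h_r) I_cl)``; the evaporative flux is scaled analogously by
    ``1/(1 + h_e R_e,cl)``.  Zero resistances leave fluxes unchanged.
    """
    f_dry = 1.0 / (1.0 + (h_c + h_r) * i_cl)
    f_evap = 1.0 / (1.0 + h_e * r_ecl)
    return dry_flux * f_dry, evap_flux * f_evap


# --------------------------------------------------------------------------
# Geometry: panels and view factors

@dataclass
class Panel:
    """A vertical rectangular radiant source.

    The panel plane is at horizontal ``distance`` from the body axis, in the
    direction ``azimuth_deg`` (0° = anterior, 90° = the body's left side),
    spanning ``width`` horizontally (centred, plus ``lateral_offset``) and
    ``height`` vertically from ``base_z``.  Its normal points back at the
    body.  ``T_r`` is its surface temperature, °C.
    """

    T_r: float
    width: float
    height: float
    distance: float
    azimuth_deg: float = 90.0
    base_z: float = 0.0
    lateral_offset: float = 0.0
    emissivity: float = 0.95

    def corners(self) -> np.ndarray:
        """Panel corner coordinates (4×3), counter-clockwise seen from body."""
        phi = math.radians(self.azimuth_deg)
        v = np.array([math.cos(phi), math.sin(phi), 0.0])
        t = np.array([-math.sin(phi), math.cos(phi), 0.0])
        c0 = self.distance * v + self.lateral_offset * t
        w2 = 0.5 * self.width
        z0, z1 = self.base_z, self.base_z + self.height
        return np.array([
            c0 + w2 * t + z0 * np.array([0, 0, 1.0]),
            c0 - w2 * t + z0 * np.array([0, 0, 1.0]),
            c0 - w2 * t + z1 * np.array([0, 0, 1.0]),
            c0 + w2 * t + z1 * np.array([0, 0, 1.0]),
        ])


def element_view_factor(point: np.ndarray, normal: np.ndarray,
                        corners: np.ndarray) -> float:
    """View factor from a differential planar element to a planar polygon.

    Contour-integral (Stokes) form: ``F = (1/2π) Σ_i γ_i (ĝ_i · n̂)`` over
    the polygon edges, with the polygon first clipped against the element's
    horizon plane.  Exact for arbitrary orientation; additive over polygon
    subdivisions by construction.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rel = np.asarray(corners, dtype=float) - np.asarray(point, dtype=float)

    # Clip the polygon against the element plane (keep n·x >= eps).
    eps = 1e-12
    d = rel @ n
    if np.all(d <= eps):
        return 0.0
    clipped: list[np.ndarray] = []
    m = len(rel)
    for i in range(m):
        a, b = rel[i], rel[(i + 1) % m]
        da, db = d[i], d[(i + 1) % m]
        if da >= eps:
            clipped.append(a)
            if db < eps:
                clipped.append(a + (b - a) * (da - eps) / (da - db))
        elif db >= eps:
            clipped.append(a + (b - a) * (da - eps) / (da - db))
    if len(clipped) < 3:
        return 0.0

    total = 0.0
    m = len(clipped)
    for i in range(m):
        a, b = clipped[i], clipped[(i + 1) % m]
        cross = np.cross(a, b)
        norm_c = np.linalg.norm(cross)
        if norm_c < 1e-300:
            continue
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        cosg = float(np.dot(a, b) / (na * nb))
        gamma = math.acos(min(1.0, max(-1.0, cosg)))
        total += gamma * float(cross @ n) / norm_c
    return min(1.0, abs(total) / (2.0 * math.pi))


@dataclass
class _Strip:
    """A flat vertical rectangular strip standing in for a curved surface."""

    center: np.ndarray      # 3-vector, centre of the strip
    normal: np.ndarray      # outward unit normal (horizontal)
    width: float            # horizontal extent, m
    height: float           # vertical extent, m

    def grid(self, nw: int, nh: int) -> np.ndarray:
        t = np.cross([0.0, 0.0, 1.0], self.normal)
        t = t / np.linalg.norm(t)
        u = (np.arange(nw) + 0.5) / nw - 0.5
        v = (np.arange(nh) + 0.5) / nh - 0.5
        pts = (self.center[None, None, :]
               + u[:, None, None] * self.width * t[None, None, :]
               + v[None, :, None] * self.height * np.array([0.0, 0.0, 1.0]))
        return pts.reshape(-1, 3)


def rect_view_factor(strip: _Strip, corners: np.ndarray,
                     nw: int = 8, nh: int = 12) -> float:
    """Area-averaged view factor from a flat strip to a polygon panel.

    Midpoint quadrature of the exact per-element contour view factor over
    the strip surface.
    """
    pts = strip.grid(nw, nh)
    F = [element_view_factor(p, strip.normal, corners) for p in pts]
    return float(np.clip(np.mean(F), 0.0, 1.0))


def view_factor(panel: Panel, *, sector_azimuth_deg: float,
                center_z: float, length: float, radius: float,
                nw: int = 8, nh: int = 12) -> float:
    """View factor from one skin sector to a radiant panel, in [0, 1].

    The sector is modelled as a flat vertical strip of height ``length`` and
    width ``radius·π/2`` (the sector arc length), offset by ``radius`` from
    the body axis along its outward normal.  Sectors whose horizon excludes
    the panel (e.g. the side facing away) receive exactly zero.
    """
    if panel.width <= 0.0 or panel.height <= 0.0:
        return 0.0
    phi = math.radians(sector_azimuth_deg)
    normal = np.array([math.cos(phi), math.sin(phi), 0.0])
    strip = _Strip(center=radius * normal + np.array([0.0, 0.0, center_z]),
                   normal=normal, width=radius * math.pi / 2.0, height=length)
    return rect_view_factor(strip, panel.corners(), nw=nw, nh=nh)


# --------------------------------------------------------------------------
# Scenario-level environment containers

@dataclass
class Stage:
    """One piecewise-constant stage of a staged exposure.

    ``T_air`` and ``P_air`` may be scalars or length-4 per-sector values
    (anterior, exterior, posterior, inferior).  ``rh`` (relative humidity,
    0–1) may be given instead of ``P_air``.  ``T_mrt`` defaults to the air
    temperature.  ``h_e`` defaults to the Lewis relation ``16.5·h_c``.
    """

    duration: float
    T_air: float | list[float]
    P_air: float | list[float] | None = None
    rh: float | None = None
    T_mrt: float | None = None
    h_c: float = 3.0
    h_r: float = 4.7
    h_e: float | None = None
    panels: list[Panel] = field(default_factory=list)

    def validate(self) -> None:
        if not self.duration > 0.0:
            raise ValueError("stage duration must be positive")
        if self.P_air is None and self.rh is None:
            raise ValueError("stage needs P_air or rh")
        for h, nm in ((self.h_c, "h_c"), (self.h_r, "h_r")):
            if not h > 0.0:
                raise ValueError(f"{nm} must be positive")
        if self.h_e is not None and not self.h_e > 0.0:
            raise ValueError("h_e must be positive")
        for p in self.panels:
            if not p.distance > 0.0:
                raise ValueError("panel distance must be positive")


@dataclass
class EnvironmentSpec:
    """Ordered list of exposure stages."""

    stages: list[Stage]

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("environment needs at least one stage")
        for st in self.stages:
            st.validate()

    @property
    def total_duration(self) -> float:
        return sum(st.duration for st in self.stages)


@dataclass
class ClothingSpec:
    """Per-segment clothing resistances (serial layer).

    ``i_cl``: intrinsic dry insulation, m²K/W; ``r_ecl``: evaporative
    resistance, m²kPa/W.  Segments absent from the maps are bare.
    """

    i_cl: dict[str, float] = field(default_factory=dict)
    r_ecl: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for d in (self.i_cl, self.r_ecl):
            for k, v in d.items():
                if v < 0.0:
                    raise ValueError(f"clothing resistance for {k} must be ≥ 0")


@dataclass
class ResolvedEnvironment:
    """A stage resolved onto a specific body: plain arrays for the RHS.

    ``rad2_terms`` holds one ``(coeff, T_r)`` pair per panel, with
    ``coeff = σ ε F_vf`` per segment-sector (n×4).
    """

    T_air: np.ndarray            # (n, 4), °C
    P_air: np.ndarray            # (n, 4), kPa
    T_mrt: float                 # °C
    h_c: float
    h_r: float
    h_e: float
    rad2_terms: list[tuple[np.ndarray, float]]
    panel_F_total: np.ndarray    # (n, 4), Σ panel view factors (≤ 1); the
                                 # MRT exchange covers the remaining 1 − ΣF
    f_dry: np.ndarray            # (n,), clothing scaling of CON+RAD
    f_evap: np.ndarray           # (n,), clothing scaling of EVA
    T_air_mean: float            # controller's ambient reference, °C
    exchange_enabled: bool = True
    respiration_enabled: bool = True
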
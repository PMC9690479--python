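"""The active system: error signals, vasomotion, sweating, shivering.

The controller senses the deviation of each segment's mean skin temperature
from its set point and of the head core temperature from its reference
(36.9 °C).  Integrated warm/cold skin signals (``Wrms``/``Clds``, weighted
by the per-segment sensitivity ``α_sk``) and the core error drive:

* vasomotion — skin blood flow per segment in Stolwijk form,
  ``ṁ = (ṁ_basal + α_sk g_dil·DL) / (1 + α_sk g_con·ST)``, clamped to the
  tabulated ``[ṁ_min, ṁ_max]``;
* sweating — a whole-body rate distributed by ``α_sw``, with the
  high-temperature dehydration corrections: each 1 % of body mass lost as
  sweat raises the sweating threshold by 0.06 °C and lowers the sensitivity
  by 0.068 kg/(h·°C);
* shivering — total power ``g_sh · (core cold error) · Clds`` distributed to
  segment cores by ``α_sh``;
* the metabolic multiplier — in ambient air at or above 39 °C metabolism
  rises 13 % per °C of core temperature above 39 °C;
* the heart-rate increment ``ΔHR = 4.75·D`` (a reported output; it does not
  feed back into the flows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .body_parameters import SegmentParameters, ThermoregParams

__all__ = [
    "ControlOutputs",
    "mean_skin_temperature",
    "metabolic_multiplier",
    "dehydration_percent",
    "heart_rate_increase",
    "sweating_rate",
    "vasomotor_skin_flow",
    "shivering_heat",
    "compute_controls",
]


def mean_skin_temperature(T_sk) -> float | np.ndarray:
    """Mean skin temperature of a segment: arithmetic mean of its 4 sectors."""
    return np.mean(np.asarray(T_sk, dtype=float), axis=-1)


def metabolic_multiplier(T_cr: float, T_a: float) -> float:
    """Heat-stress metabolic multiplier (≥ 1).

    Below 39 °C ambient the multiplier is 1.  At or above, metabolism grows
    13 % per °C of core temperature above 39 °C, floored at 1 so a hot
    environment never suppresses basal metabolism.
    """
    if T_a < 39.0:
        return 1.0
    return max(1.0, 1.0 + 0.13 * (T_cr - 39.0))


def dehydration_percent(sweat_cumulative: float, body_mass_ref: float = 74.30) -> float:
    """Cumulative water loss as % of the reference body mass (kg in, % out)."""
    return 100.0 * sweat_cumulative / body_mass_ref


def heart_rate_increase(D: float) -> float:
    """Dehydration-driven heart rate increment, beats/min: ``ΔHR = 4.75·D``."""
    return 4.75 * D


def sweating_rate(T_head: float, Wrms: float, Clds: float, D: float,
                  T_head_set: float = 37.0) -> float:
    """Whole-body sweat production rate, kg/h.

    ``rate = (0.2898 − 0.068 D)(T_head − T_head,set − 0.06 D)
    + 0.03364·Wrms − Clds``, floored at 0.  Dehydration ``D`` (in %) shifts
    the onset threshold up by 0.06 °C per % and degrades the sensitivity by
    0.068 kg/(h·°C) per %; beyond D ≈ 4.26 % the sensitivity would turn
    negative and is floored at zero (with a warning — outside the model's
    validated range).
    """
    sensitivity = 0.2898 - 0.068 * D
    if sensitivity < 0.0:
        warnings.warn(
            f"dehydration D = {D:.2f}% exceeds the range where the sweating "
            "sensitivity stays positive; flooring it at 0", stacklevel=2)
        sensitivity = 0.0
    rate = sensitivity * (T_head - T_head_set - 0.06 * D) + 0.03364 * Wrms - Clds
    return max(0.0, rate)


def vasomotor_skin_flow(m_basal: float, m_min: float, m_max: float,
                        alpha_sk: float, DL: float, ST: float) -> float:
    """Skin blood flow of one segment, cm³/h (Stolwijk form, clamped).

    ``DL`` is the warm (dilation) drive in cm³/h, ``ST`` the cold
    (constriction) drive (dimensionless); ``α_sk`` distributes both.
    """
    flow = (m_basal + alpha_sk * DL) / (1.0 + alpha_sk * ST)
    return float(min(max(flow, m_min), m_max))


def shivering_heat(cld_core: float, Clds: float, g_sh: float,
                   alpha_sh: np.ndarray) -> tuple[float, np.ndarray]:
    """Total shivering power (W, ≥ 0) and its distribution over cores."""
    total = max(0.0, g_sh * cld_core * Clds)
    return total, total * np.asarray(alpha_sh, dtype=float)


@dataclass
class ControlOutputs:
    """All controller outputs consumed by the passive system."""

    skin_flow_cm3h: np.ndarray     # (n,) per-segment skin perfusion
    sweat_total_kgh: float         # whole-body sweat production
    sweat_sector_kgh: np.ndarray   # (n, 4) per-sector sweat allocation
    shiver_w: np.ndarray           # (n,) per-core shivering heat
    metabolic_multiplier: float
    Wrms: float
    Clds: float
    D: float
    dHR: float


def compute_controls(T_cr: np.ndarray, T_sk: np.ndarray, sweat_cumulative: float,
                     T_air_mean: float, thermo: ThermoregParams,
                     segments: list[SegmentParameters],
                     head_index: int = 0,
                     metabolism_enabled: bool = True) -> ControlOutputs:
    """Evaluate the full active system for the current body state.

    ``T_cr`` (n,) and ``T_sk`` (n, 4) in °C; ``sweat_cumulative`` in kg;
    ``T_air_mean`` is the stage's sector-averaged air temperature used by
    the metabolic-multiplier branch.  With ``metabolism_enabled=False``
    (adiabatic diagnostics) shivering and the multiplier are suppressed.
    """
    names = [s.name for s in segments]
    a_sk = np.array([thermo.alpha_sk[n] for n in names])
    a_sh = np.array([thermo.alpha_sh[n] for n in names])
    a_sw = np.array([thermo.alpha_sw[n] for n in names])
    T_sk0 = np.array([thermo.T_sk0[n] for n in names])

    err = mean_skin_temperature(T_sk) - T_sk0
    wrm = np.maximum(err, 0.0)
    cld = np.maximum(-err, 0.0)
    Wrms = float(a_sk @ wrm)
    Clds = float(a_sk @ cld)

    T_head = float(T_cr[head_index])
    wrm_cr = max(0.0, T_head - thermo.T_cr_set_head)
    cld_cr = max(0.0, thermo.T_cr_set_head - T_head)

    DL = thermo.g_dil_cr * wrm_cr + thermo.g_dil_sk * Wrms
    ST = thermo.g_con_cr * cld_cr + thermo.g_con_sk * Clds
    flows = np.array([
        vasomotor_skin_flow(s.m_sk_basal, s.m_sk_min, s.m_sk_max,
                            a_sk[j], DL, ST)
        for j, s in enumerate(segments)])

    D = dehydration_percent(sweat_cumulative, thermo.body_mass_ref)
    sweat_total = sweating_rate(T_head, Wrms, Clds, D, thermo.T_head_set_sweat)
    sweat_sector = sweat_total * a_sw[:, None] / 4.0 * np.ones((1, 4))

    if metabolism_enabled:
        mult = metabolic_multiplier(T_head, T_air_mean)
        _, shiver = shivering_heat(cld_cr, Clds, thermo.g_sh, a_sh)
    else:
        mult = 1.0
        shiver = np.zeros(len(segments))

    return ControlOutputs(
        skin_flow_cm3h=flows,
        sweat_total_kgh=sweat_total,
        sweat_sector_kgh=sweat_sector,
        shiver_w=shiver,
        metabolic_multiplier=mult,
        Wrms=Wrms, Clds=Clds, D=D, dHR=heart_rate_increase(D),
    )
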
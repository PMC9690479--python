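"""Per-segment physical and physiological constants of the standard body.

The body is divided into 15 cylindrical segments (head, chest, abdomen and
left/right upper arms, forearms, hands, thighs, calves, feet), each carrying a
core, an arterial and a venous blood node, and four angular skin sectors
(anterior, exterior, posterior, inferior) — 105 temperature nodes in total.

This module houses the passive constants of every segment (surface area,
metabolic rates, node heat capacitances, core–skin conductance, skin blood
flow limits) and the set points and distribution coefficients of the
thermoregulatory controller, together with loading, validation and
(de)serialization helpers.

Paired limb segments share one parameter row: both the passive constants and
the controller distribution coefficients are per side, so the distribution
columns sum to ≈ 1 over all 15 segments with the pairs counted twice.

Geometry (segment length, skin radius, skin thickness and conductivity) is
not part of the tabulated data; defaults are derived from the surface area of
a cylinder of canonical anthropometric length (``r = A / (2π L_n)``) with a
1 mm skin layer of conductivity 0.47 W/(m·K).  All fields can be overridden
from a scenario file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace, asdict
from typing import Iterable

__all__ = [
    "SEGMENT_NAMES",
    "SECTOR_NAMES",
    "SegmentParameters",
    "ThermoregParams",
    "ParameterError",
    "load_default_body",
    "validate_parameters",
    "body_to_dict",
    "body_from_dict",
    "apply_overrides",
]

#: Canonical segment order.  All state vectors and per-segment arrays use it.
SEGMENT_NAMES = (
    "head",
    "chest",
    "abdomen",
    "left_upper_arm",
    "right_upper_arm",
    "left_forearm",
    "right_forearm",
    "left_hand",
    "right_hand",
    "left_thigh",
    "right_thigh",
    "left_calf",
    "right_calf",
    "left_foot",
    "right_foot",
)

#: Angular skin sectors, in ring order (the ring is periodic).
SECTOR_NAMES = ("anterior", "exterior", "posterior", "inferior")


class ParameterError(ValueError):
    """Raised when a parameter set violates a physical invariant."""


@dataclass
class SegmentParameters:
    """Passive constants of one body segment.

    Parameters
    ----------
    name
        Segment label, one of :data:`SEGMENT_NAMES`.
    A
        Skin surface area, m².  Each sector exposes ``A/4``.
    M_cr, M_sk
        Basal core metabolic rate and total skin metabolic rate, W.  The skin
        rate is shared equally by the four sectors.
    W_cr
        Mechanical work rate extracted from the core, W (0 at rest).
    C_cr, C_bl_a, C_bl_v, C_sk
        Heat capacitances of the core, arterial, venous and (whole-segment)
        skin nodes, J/K.  Each sector carries ``C_sk/4``.
    K_cr_sk
        Total core→skin conductance, W/K; each sector gets ``K_cr_sk/4``.
    m_sk_basal, m_sk_min, m_sk_max
        Skin blood flow at the neutral point and at full vasoconstriction /
        vasodilation, cm³/h.
    L_n
        Segment length, m.
    r
        Radius of the skin layer, m.
    th_sk
        Skin layer thickness, m.
    K_sk
        Skin thermal conductivity, W/(m·K).
    epsilon
        Skin/clothing long-wave emissivity.
    """

    name: str
    A: float
    M_cr: float
    M_sk: float
    C_cr: float
    C_bl_a: float
    C_bl_v: float
    C_sk: float
    K_cr_sk: float
    m_sk_basal: float
    m_sk_min: float
    m_sk_max: float
    L_n: float
    r: float
    W_cr: float = 0.0
    th_sk: float = 1.0e-3
    K_sk: float = 0.47
    epsilon: float = 0.95


@dataclass
class ThermoregParams:
    """Set points, distribution coefficients and controller constants.

    ``T_sk0``/``alpha_*`` are keyed by segment name (per side for paired
    limbs).  ``alpha_sk`` is the skin sensitivity weight used both to build
    the integrated warm/cold skin signals and to distribute the vasomotor
    drives; ``alpha_sh`` and ``alpha_sw`` distribute shivering heat and sweat
    production.

    The controller gains (``g_*``) are calibration constants: the vasomotor
    and shivering internals are inherited model structure, not tabulated
    data.  Defaults are calibrated so that a resting unclothed body in a
    29 °C / 50 % RH environment settles at a head-core temperature of
    36.6–37.1 °C with a mean skin temperature of 33–35 °C.
    """

    T_sk0: dict[str, float]
    alpha_sk: dict[str, float]
    alpha_sh: dict[str, float]
    alpha_sw: dict[str, float]
    T_cr_set_head: float = 36.9     # vasomotor / shivering core reference, °C
    T_head_set_sweat: float = 37.0  # sweating set point, °C
    c_bl: float = 4000.0            # blood specific heat, J/(kg·K)
    body_mass_ref: float = 74.30    # dehydration denominator, kg
    blood_density: float = 1059.0   # kg/m³, converts cm³/h to kg/s
    # -- calibrated controller gains -------------------------------------
    g_dil_cr: float = 117000.0      # vasodilation drive per K warm core, cm³/(h·K)
    g_dil_sk: float = 7500.0        # vasodilation drive per K warm skin, cm³/(h·K)
    g_con_cr: float = 400.0         # vasoconstriction drive per K cold core, 1/K
    g_con_sk: float = 20.0          # vasoconstriction drive per K cold skin, 1/K
    g_sh: float = 24.4              # shivering gain, W/K² (core cold × skin cold)
    core_perfusion_total: float = 267000.0  # resting whole-body core blood flow, cm³/h


# --------------------------------------------------------------------------
# Tabulated per-segment data.  Paired limbs replicate the single row.
# Columns: A, M_cr, M_sk, C_cr, C_bl_a, C_bl_v, C_sk, K_cr_sk,
#          m_sk_basal, m_sk_min, m_sk_max
_PASSIVE_TABLE: dict[str, tuple[float, ...]] = {
    "head":      (0.140, 18.433, 0.219, 12247.1, 810.5, 2482.1, 1710.2, 1.848, 6050.0, 4518.0, 16552.0),
    "chest":     (0.336, 5.95, 0.6, 36732.1, 2266.8, 6941.9, 13624.8, 4.921, 3441.5, 0.0, 33246.0),
    "abdomen":   (0.221, 46.86, 0.6, 67160.5, 566.7, 1735.5, 13624.8, 4.921, 2272.5, 0.0, 21953.0),
    "upper_arm": (0.096, 1.062, 0.182, 6707.9, 49.6, 151.9, 1284.02, 1.304, 910.0, 0.0, 8319.0),
    "forearm":   (0.063, 0.593, 0.101, 3750.1, 32.3, 99.1, 717.9, 0.913, 508.0, 0.0, 5553.0),
    "hand":      (0.050, 0.095, 0.093, 791.4, 21.4, 65.7, 723.5, 0.545, 1114.0, 627.0, 4454.0),
    "thigh":     (0.209, 1.708, 0.343, 11926.3, 93.1, 285.1, 4133.9, 1.564, 1456.0, 0.0, 12453.0),
    "calf":      (0.112, 0.754, 0.153, 5262.3, 36.8, 112.6, 1850.8, 1.216, 651.0, 0.0, 8253.0),
    "foot":      (0.056, 0.146, 0.127, 1465.3, 18.7, 57.2, 1347.4, 0.631, 934.0, 301.0, 5278.0),
}

# Columns: T_sk0, alpha_sk, alpha_sh, alpha_sw — per side for paired limbs;
# the three alpha columns sum to ≈ 1 over all fifteen segments.
_THERMOREG_TABLE: dict[str, tuple[float, float, float, float]] = {
    "head":      (35.6, 0.07, 0.02, 0.081),
    "chest":     (33.6, 0.281, 0.485, 0.275),
    "abdomen":   (33.3, 0.212, 0.365, 0.206),
    "upper_arm": (33.4, 0.023, 0.004, 0.051),
    "forearm":   (34.6, 0.012, 0.026, 0.026),
    "hand":      (35.2, 0.092, 0.0, 0.016),
    "thigh":     (33.8, 0.05, 0.023, 0.073),
    "calf":      (33.4, 0.025, 0.012, 0.036),
    "foot":      (33.9, 0.017, 0.0, 0.018),
}

#: Canonical anthropometric segment lengths, m (cylinder model).
_SEGMENT_LENGTHS: dict[str, float] = {
    "head": 0.20,
    "chest": 0.30,
    "abdomen": 0.30,
    "upper_arm": 0.30,
    "forearm": 0.30,
    "hand": 0.20,
    "thigh": 0.40,
    "calf": 0.40,
    "foot": 0.20,
}


def _base_name(name: str) -> str:
    """Strip a left_/right_ prefix, mapping a segment to its parameter row."""
    for prefix in ("left_", "right_"):
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


def load_default_body() -> tuple[list[SegmentParameters], ThermoregParams]:
    """Build the 15-segment standard body from the tabulated defaults.

    Returns the segments in canonical order plus the thermoregulatory
    parameter set.  Paired limb segments replicate the single tabulated row.
    """
    segments: list[SegmentParameters] = []
    for name in SEGMENT_NAMES:
        base = _base_name(name)
        (A, M_cr, M_sk, C_cr, C_bl_a, C_bl_v, C_sk, K_cr_sk,
         m_basal, m_min, m_max) = _PASSIVE_TABLE[base]
        L_n = _SEGMENT_LENGTHS[base]
        r = A / (2.0 * math.pi * L_n)
        segments.append(SegmentParameters(
            name=name, A=A, M_cr=M_cr, M_sk=M_sk,
            C_cr=C_cr, C_bl_a=C_bl_a, C_bl_v=C_bl_v, C_sk=C_sk,
            K_cr_sk=K_cr_sk, m_sk_basal=m_basal, m_sk_min=m_min,
            m_sk_max=m_max, L_n=L_n, r=r,
        ))
    thermo = ThermoregParams(
        T_sk0={n: _THERMOREG_TABLE[_base_name(n)][0] for n in SEGMENT_NAMES},
        alpha_sk={n: _THERMOREG_TABLE[_base_name(n)][1] for n in SEGMENT_NAMES},
        alpha_sh={n: _THERMOREG_TABLE[_base_name(n)][2] for n in SEGMENT_NAMES},
        alpha_sw={n: _THERMOREG_TABLE[_base_name(n)][3] for n in SEGMENT_NAMES},
    )
    return segments, thermo


def validate_parameters(
    segments: Iterable[SegmentParameters],
    thermo: ThermoregParams,
    strict: bool = True,
) -> list[str]:
    """Check every parameter invariant; return the list of violations.

    With ``strict=True`` (default) any violation raises
    :class:`ParameterError` carrying the full report.
    """
    violations: list[str] = []
    segments = list(segments)
    for seg in segments:
        for f in ("A", "C_cr", "C_bl_a", "C_bl_v", "C_sk", "L_n", "r", "th_sk"):
            v = getattr(seg, f)
            if not v > 0.0:
                kind = "capacitance" if f.startswith("C") else f
                violations.append(
                    f"{seg.name}.{f}: {kind} must be positive (got {v!r})")
        if not (seg.m_sk_min <= seg.m_sk_basal <= seg.m_sk_max):
            violations.append(
                f"{seg.name}: skin blood flow ordering violated, need "
                f"m_sk_min <= m_sk_basal <= m_sk_max, got "
                f"({seg.m_sk_min}, {seg.m_sk_basal}, {seg.m_sk_max})")
        if not (0.0 <= seg.epsilon <= 1.0):
            violations.append(f"{seg.name}.epsilon: must be in [0, 1]")

    names = [s.name for s in segments]
    for attr in ("alpha_sk", "alpha_sh", "alpha_sw"):
        coeffs = getattr(thermo, attr)
        missing = [n for n in names if n not in coeffs]
        if missing:
            violations.append(f"{attr}: missing segments {missing}")
            continue
        total = sum(coeffs[n] for n in names)
        if len(names) == len(SEGMENT_NAMES) and not (0.99 <= total <= 1.01):
            violations.append(
                f"{attr}: distribution coefficients sum to {total:.4f}, "
                f"expected ≈ 1 over the 15 segments")
    for n in names:
        t0 = thermo.T_sk0.get(n)
        if t0 is None:
            violations.append(f"T_sk0: missing segment {n}")
        elif not (30.0 <= t0 <= 37.0):
            violations.append(f"T_sk0[{n}] = {t0} outside the [30, 37] °C band")

    if strict and violations:
        raise ParameterError("invalid body parameters:\n" + "\n".join(violations))
    return violations


# --------------------------------------------------------------------------
# (De)serialization — round-trips bit-exactly through plain dicts / YAML.

def body_to_dict(segments: Iterable[SegmentParameters],
                 thermo: ThermoregParams) -> dict:
    """Serialize a body to a plain nested dict (YAML/JSON friendly)."""
    return {
        "segments": {s.name: {f.name: getattr(s, f.name)
                              for f in fields(s) if f.name != "name"}
                     for s in segments},
        "thermoregulation": asdict(thermo),
    }


def body_from_dict(data: dict) -> tuple[list[SegmentParameters], ThermoregParams]:
    """Inverse of :func:`body_to_dict` (canonical segment order restored)."""
    seg_data = data["segments"]
    names = (SEGMENT_NAMES if set(seg_data) == set(SEGMENT_NAMES)
             else list(seg_data))
    segments = [SegmentParameters(name=name, **seg_data[name])
                for name in names]
    thermo = ThermoregParams(**data["thermoregulation"])
    return segments, thermo


def apply_overrides(
    segments: list[SegmentParameters],
    thermo: ThermoregParams,
    overrides: dict[str, dict[str, float]] | None,
) -> tuple[list[SegmentParameters], ThermoregParams]:
    """Apply per-segment field overrides (keyed segment → field → value).

    Unknown segment or field names raise :class:`ParameterError`; the input
    objects are not mutated.
    """
    if not overrides:
        return segments, thermo
    by_name = {s.name: s for s in segments}
    valid_fields = {f.name for f in fields(SegmentParameters)} - {"name"}
    out = list(segments)
    for seg_name, seg_over in overrides.items():
        if seg_name not in by_name:
            raise ParameterError(f"unknown segment {seg_name!r} in overrides")
        bad = set(seg_over) - valid_fields
        if bad:
            raise ParameterError(
                f"unknown field(s) {sorted(bad)} for segment {seg_name!r}")
        idx = [s.name for s in out].index(seg_name)
        out[idx] = replace(by_name[seg_name], **seg_over)
    return out, thermo
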
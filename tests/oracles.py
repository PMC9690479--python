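"""Independent brute-force oracles for the test suite.

Everything here is deliberately slow, scalar and loop-based, sharing no code
with the production modules: a hand-coded energy balance for a two-segment
toy body, saturation pressure in Buck (not Antoine) form, view factors by
adaptive quadrature of the raw kernel and by the classical corner formula,
and a reproducible physiological random-state generator.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.integrate

SIGMA = 5.670374419e-8
LAMBDA = 2.426e6


def buck_saturation_pressure(T_c: float) -> float:
    """Arden Buck saturation vapor pressure over water, kPa."""
    return 0.61121 * math.exp((18.678 - T_c / 234.5) * (T_c / (257.14 + T_c)))


# --------------------------------------------------------------------------
# Two-segment toy body, scalar energy balances

def make_toy_body() -> dict:
    """A chest-like root plus one limb, all parameters small round numbers."""
    return {
        "names": ["chest", "limb"],
        "A": [0.3, 0.1],
        "M_cr": [50.0, 2.0],
        "M_sk": [1.0, 0.2],
        "W_cr": [0.5, 0.0],
        "C_cr": [30000.0, 6000.0],
        "C_a": [2000.0, 50.0],
        "C_v": [6000.0, 150.0],
        "C_sk": [12000.0, 1200.0],
        "K_cr_sk": [4.0, 1.3],
        "m_basal": [3000.0, 900.0],
        "m_min": [0.0, 0.0],
        "m_max": [30000.0, 8000.0],
        "L_n": [0.3, 0.3],
        "r": [0.12, 0.05],
        "th_sk": [1.0e-3, 1.0e-3],
        "K_sk": [0.47, 0.47],
        "eps": [0.95, 0.95],
        "parent": [0, 0],
        "root": 0,
        "h_a": [20.0, 0.5],
        "h_v": [60.0, 1.5],
        "c_bl": 4000.0,
        "rho_bl": 1059.0,
        "core_perfusion_total": 20000.0,  # cm³/h
        "i_cl": [0.05, 0.0],
        "r_ecl": [0.008, 0.0],
        "alpha_sw": [0.5, 0.5],
    }


def make_toy_env(n: int = 2) -> dict:
    """Angularly non-uniform toy environment with one radiant panel."""
    return {
        "T_air": np.array([[25.0, 30.0, 22.0, 28.0],
                           [35.0, 40.0, 20.0, 45.0]][:n]),
        "P_air": np.array([[1.5, 2.5, 1.0, 3.0],
                           [2.0, 4.0, 1.2, 3.5]][:n]),
        "T_mrt": 30.0,
        "h_c": 3.0,
        "h_r": 4.7,
        "h_e": 49.5,
        # one panel: per-sector view factors and its temperature
        "panel_F": np.array([[0.5, 0.2, 0.0, 0.0],
                             [0.3, 0.0, 0.0, 0.1]][:n]),
        "panel_T_r": 60.0,
        "panel_eps": 0.9,
    }


def _antoine(T_c: float) -> float:
    # same saturation curve the production code documents; restated here so
    # the oracle remains self-contained
    return 0.133322 * 10.0 ** (8.07131 - 1730.63 / (233.426 + T_c))


def _redistribute(T_sk4, total):
    mean = sum(T_sk4) / 4.0
    delta = [t - mean for t in T_sk4]
    pos = sum(d for d in delta if d > 0.0)
    q = total / 4.0
    if pos <= 0.0:
        return [q, q, q, q]
    m = [q * (1.0 + d / pos) for d in delta]
    if any(x < 0.0 for x in m):
        m = [max(x, 0.0) for x in m]
        s = sum(m)
        if s > 0.0:
            m = [x * total / s for x in m]
    return m


def scalar_rhs_oracle(body: dict, y: np.ndarray, env: dict,
                      controls: dict) -> np.ndarray:
    """Unvectorized evaluation of every energy-balance term of the toy body.

    ``controls`` carries prescribed controller outputs: ``skin_flow_cm3h``
    (per segment), ``sweat_total_kgh``, ``shiver_w`` (per segment) and
    ``mult``.  Layout of ``y`` matches the production state vector.
    """
    n = len(body["names"])
    T_cr = [float(y[j]) for j in range(n)]
    T_a = [float(y[n + j]) for j in range(n)]
    T_v = [float(y[2 * n + j]) for j in range(n)]
    T_sk = [[float(y[3 * n + 4 * j + i]) for i in range(4)] for j in range(n)]
    c = body["c_bl"]
    to_kgps = 1e-6 * body["rho_bl"] / 3600.0
    mult = controls["mult"]

    # blood flows
    m_sk = [_redistribute(T_sk[j],
                          controls["skin_flow_cm3h"][j] * to_kgps)
            for j in range(n)]
    m_sk_tot = [sum(m_sk[j]) for j in range(n)]
    M_sum = sum(body["M_cr"])
    m_cr = [body["core_perfusion_total"] * body["M_cr"][j] / M_sum * to_kgps
            for j in range(n)]
    local = [m_cr[j] + m_sk_tot[j] for j in range(n)]
    # branch flows leaf→root
    m_a = list(local)
    depth_order = sorted(range(n), key=lambda j: -_depth(body, j))
    for j in depth_order:
        if j != body["root"]:
            m_a[body["parent"][j]] += m_a[j]

    dy = np.zeros(7 * n + 1)
    for j in range(n):
        # clothing factors
        f_dry = 1.0 / (1.0 + (env["h_c"] + env["h_r"]) * body["i_cl"][j])
        f_evap = 1.0 / (1.0 + env["h_e"] * body["r_ecl"][j])
        A_sec = body["A"][j] / 4.0

        CON, EVA, RAD = [], [], []
        for i in range(4):
            CON.append(A_sec * env["h_c"] * (T_sk[j][i] - env["T_air"][j][i])
                       * f_dry)
            F = env["panel_F"][j][i]
            rad = A_sec * env["h_r"] * (T_sk[j][i] - env["T_mrt"]) * (1.0 - F)
            rad += A_sec * SIGMA * body["eps"][j] * env["panel_eps"] * F * (
                (T_sk[j][i] + 273.15) ** 4 - (env["panel_T_r"] + 273.15) ** 4)
            RAD.append(rad * f_dry)
            psat = _antoine(T_sk[j][i])
            he_eff = env["h_e"] * f_evap
            cap = A_sec * he_eff * max(psat - env["P_air"][j][i], 0.0)
            demand = (controls["sweat_total_kgh"] * body["alpha_sw"][j] / 4.0
                      * LAMBDA / 3600.0)
            if cap > 0.0:
                w = min(0.06 + 0.94 * demand / cap, 1.0)
            else:
                w = 0.06
            EVA.append(w * cap)

        RES = 0.0
        if j == body["root"]:
            Ta_mean = sum(env["T_air"][j]) / 4.0
            Pa_mean = sum(env["P_air"][j]) / 4.0
            M_res = body["M_cr"][j] * mult
            RES = (0.0014 * M_res * (34.0 - Ta_mean)
                   + 0.0173 * M_res * (5.87 - Pa_mean))

        K_sec = body["K_cr_sk"][j] / 4.0
        Q_cr_sk = [K_sec * (T_cr[j] - T_sk[j][i]) for i in range(4)]
        Q_perf_cr_sk = [m_sk[j][i] * c * (T_cr[j] - T_sk[j][i])
                        for i in range(4)]
        Q_cr_a = body["h_a"][j] * (T_cr[j] - T_a[j])
        Q_cr_v = body["h_v"][j] * (T_cr[j] - T_v[j])
        Q_perf_a_cr = local[j] * c * (T_cr[j] - T_a[j])
        Q_perf_cr_v = local[j] * c * (T_cr[j] - T_v[j])

        M_core = body["M_cr"][j] * mult + controls["shiver_w"][j]
        dy[j] = (M_core - body["W_cr"][j] - sum(Q_cr_sk) - sum(Q_perf_cr_sk)
                 - Q_perf_a_cr - Q_cr_a - Q_cr_v - RES) / body["C_cr"][j]

        T_up = T_a[body["parent"][j]] if j != body["root"] else T_v[j]
        dy[n + j] = (Q_cr_a + m_a[j] * c * (T_up - T_a[j])) / body["C_a"][j]

        q_v = Q_cr_v + Q_perf_cr_v
        for k in range(n):
            if k != body["root"] and body["parent"][k] == j:
                q_v += m_a[k] * c * (T_v[k] - T_v[j])
        dy[2 * n + j] = q_v / body["C_v"][j]

        k_ang = (body["K_sk"][j] * body["L_n"][j] * body["th_sk"][j]
                 / body["r"][j] ** 2 / (math.pi / 2.0) ** 2)
        for i in range(4):
            ang = k_ang * (T_sk[j][(i + 1) % 4] - 2.0 * T_sk[j][i]
                           + T_sk[j][(i - 1) % 4])
            dy[3 * n + 4 * j + i] = (
                ang + body["M_sk"][j] / 4.0 * mult + Q_cr_sk[i]
                + Q_perf_cr_sk[i] - CON[i] - EVA[i] - RAD[i]
            ) / (body["C_sk"][j] / 4.0)

    dy[7 * n] = controls["sweat_total_kgh"] / 3600.0
    return dy


def _depth(body: dict, j: int) -> int:
    d = 0
    while j != body["root"]:
        j = body["parent"][j]
        d += 1
    return d


# --------------------------------------------------------------------------
# View-factor oracles

def dA_to_rect_quadrature(point, normal, corners) -> float:
    """View factor from a planar element to a rectangle by scipy dblquad.

    Direct numerical integration of ``cosθ1 cosθ2 / (π s²)`` over the
    rectangle, with negative cosines clipped (horizon).
    """
    p = np.asarray(point, float)
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    c = np.asarray(corners, float)
    eu = c[1] - c[0]
    ev = c[3] - c[0]
    n2 = np.cross(eu, ev)
    n2 = n2 / np.linalg.norm(n2)
    if np.dot(p - c[0], n2) < 0:
        n2 = -n2

    def kernel(v, u):
        q = c[0] + u * eu + v * ev
        s = q - p
        d2 = float(s @ s)
        cos1 = float(s @ n) / math.sqrt(d2)
        cos2 = float(-s @ n2) / math.sqrt(d2)
        if cos1 <= 0.0 or cos2 <= 0.0:
            return 0.0
        return cos1 * cos2 / (math.pi * d2)

    area = np.linalg.norm(np.cross(eu, ev))
    val, _ = scipy.integrate.dblquad(kernel, 0.0, 1.0, 0.0, 1.0,
                                     epsabs=1e-10, epsrel=1e-10)
    return val * area


def parallel_corner_formula(a: float, b: float, c: float) -> float:
    """dA → corner-aligned parallel rectangle (a × b at distance c)."""
    A, B = a / c, b / c
    return (A / math.sqrt(1 + A * A) * math.atan(B / math.sqrt(1 + A * A))
            + B / math.sqrt(1 + B * B) * math.atan(A / math.sqrt(1 + B * B))
            ) / (2.0 * math.pi)


def dA_parallel_rect(dx0, dx1, dy0, dy1, c) -> float:
    """dA at origin (normal +z) to rectangle [dx0,dx1]×[dy0,dy1] at z = c.

    Corner decomposition (signed additivity of the corner formula).
    """
    def corner(x, y):
        if x == 0.0 or y == 0.0:
            return 0.0
        return math.copysign(1.0, x * y) * parallel_corner_formula(
            abs(x), abs(y), c)
    return (corner(dx1, dy1) - corner(dx0, dy1)
            - corner(dx1, dy0) + corner(dx0, dy0))


def parallel_rect_to_rect(w1, h1, w2, h2, d, n=256) -> float:
    """Directly opposed, co-axial parallel rectangles by outer midpoint
    quadrature over surface 1 with the exact corner formula inside."""
    xs = (np.arange(n) + 0.5) / n * w1 - w1 / 2.0
    zs = (np.arange(n) + 0.5) / n * h1 - h1 / 2.0
    total = 0.0
    for x in xs:
        for z in zs:
            total += dA_parallel_rect(-w2 / 2.0 - x, w2 / 2.0 - x,
                                      -h2 / 2.0 - z, h2 / 2.0 - z, d)
    return total / (n * n)


# --------------------------------------------------------------------------
# Random physiological states

def random_state_generator(seed: int, n_segments: int = 15) -> np.ndarray:
    """Reproducible random state vector in physiological ranges.

    Core 36–40 °C, vessels 34–39 °C, skin 30–41 °C, cumulative sweat such
    that dehydration stays within 0–3 % of a 74.30 kg body.
    """
    rng = np.random.default_rng(seed)
    n = n_segments
    y = np.empty(7 * n + 1)
    y[0:n] = rng.uniform(36.0, 40.0, n)
    y[n:3 * n] = rng.uniform(34.0, 39.0, 2 * n)
    y[3 * n:7 * n] = rng.uniform(30.0, 41.0, 4 * n)
    y[7 * n] = rng.uniform(0.0, 0.03 * 74.30)
    return y
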
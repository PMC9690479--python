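"""Passive system: per-node balances, redistribution, conservation, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioheatsim.passive_body import (BodyState, assemble_rhs, core_rhs,
                                     perfusion_redistribution,
                                     respiratory_heat_loss, skin_sector_rhs)
from bioheatsim.thermoregulation import ControlOutputs

from conftest import toy_resolved_env
from oracles import make_toy_env, random_state_generator, scalar_rhs_oracle


# --------------------------------------------------------------------------
# respiratory heat loss

@pytest.mark.parametrize("M, T, P, expected", [
    (123.0, 34.0, 5.87, 0.0),          # both terms vanish
    (0.0, 10.0, 1.0, 0.0),             # no metabolism, no loss
    (100.0, 24.0, 2.0, 0.0014 * 100 * 10 + 0.0173 * 100 * 3.87),
])
def test_respiratory_heat_loss(M, T, P, expected):
    assert respiratory_heat_loss(M, T, P) == pytest.approx(expected, abs=1e-12)


def test_respiratory_heat_gain_in_hot_humid_air():
    # hot saturated air warms the airways: a physical heat gain
    assert respiratory_heat_loss(100.0, 45.0, 7.0) < 0.0


# --------------------------------------------------------------------------
# core balance

def test_core_rhs_equilibrium_is_zero():
    z = np.zeros(4)
    assert core_rhs(0.0, 0.0, 1000.0, z, z, 0.0, 0.0, 0.0) == 0.0


def test_core_rhs_head_metabolic_heating_rate():
    # only metabolism acting on the head core: dT/dt = M_cr / C_cr
    z = np.zeros(4)
    got = core_rhs(18.433, 0.0, 12247.1, z, z, 0.0, 0.0, 0.0)
    assert got == pytest.approx(18.433 / 12247.1, rel=1e-12)


def test_core_rhs_subtracts_all_outgoing_flows():
    got = core_rhs(10.0, 1.0, 100.0, np.full(4, 0.5), np.full(4, 0.25),
                   1.0, 0.5, 0.5, RES=1.0)
    assert got == pytest.approx((10 - 1 - 2.0 - 1.0 - 1 - 0.5 - 0.5 - 1) / 100)


# --------------------------------------------------------------------------
# skin sector balance / angular ring

def test_angular_conduction_vanishes_for_equal_sectors():
    got = skin_sector_rhs([34.0] * 4, 0, 5.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 100.0)
    assert got == 0.0


def test_angular_conduction_antisymmetric_pattern():
    # (T, T+d, T, T-d): sectors 1 and 3 receive equal and opposite conduction
    ring = [34.0, 35.0, 34.0, 33.0]
    k, C = 2.0, 100.0
    d1 = skin_sector_rhs(ring, 1, k, 0, 0, 0, 0, 0, 0, C)
    d3 = skin_sector_rhs(ring, 3, k, 0, 0, 0, 0, 0, 0, C)
    assert d1 == pytest.approx(-d3, rel=1e-12)
    total = sum(skin_sector_rhs(ring, i, k, 0, 0, 0, 0, 0, 0, C)
                for i in range(4))
    assert total == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(28.0, 42.0), min_size=4, max_size=4))
def test_angular_conduction_conserves_on_ring(ring):
    # periodic second-difference stencil sums to zero for any temperatures
    total = sum(skin_sector_rhs(ring, i, 3.7, 0, 0, 0, 0, 0, 0, 1.0)
                for i in range(4))
    assert total == pytest.approx(0.0, abs=1e-9)


# --------------------------------------------------------------------------
# perfusion redistribution

def test_redistribution_isothermal_equal_split():
    np.testing.assert_allclose(perfusion_redistribution([34.0] * 4, 400.0),
                               [100.0] * 4)


def test_redistribution_hand_example():
    # delta = (1, 0, 0, -1), sum of positive deltas = 1
    got = perfusion_redistribution([35.0, 34.0, 34.0, 33.0], 400.0)
    np.testing.assert_allclose(got, [200.0, 100.0, 100.0, 0.0], atol=1e-12)


def test_redistribution_clips_negative_and_conserves():
    # delta = (3, -1, -1, -1) stays positive; (1,1,1,-3)/scaled clips
    got = perfusion_redistribution([37.0, 35.0, 35.0, 29.0], 400.0)
    assert np.all(got >= 0.0)
    assert got.sum() == pytest.approx(400.0, abs=1e-10)


def test_redistribution_rejects_negative_total():
    with pytest.raises(ValueError):
        perfusion_redistribution([34.0] * 4, -1.0)


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(25.0, 45.0), min_size=4, max_size=4),
    st.floats(0.0, 30000.0),
)
def test_redistribution_conserves_total(temps, total):
    got = perfusion_redistribution(temps, total)
    assert got.sum() == pytest.approx(total, abs=max(1e-12, 1e-12 * total))
    assert np.all(got >= -1e-15)


def test_redistribution_favors_hotter_sectors():
    got = perfusion_redistribution([36.0, 34.0, 34.0, 32.0], 400.0)
    assert got[0] > got[1] == got[2] > got[3]


# --------------------------------------------------------------------------
# state container

def test_state_vector_roundtrip():
    y = random_state_generator(3)
    st_ = BodyState.from_vector(y, 15)
    np.testing.assert_array_equal(st_.to_vector(), y)


def test_state_check_rejects_out_of_band():
    y = random_state_generator(4)
    y[10] = 75.0
    with pytest.raises(ValueError, match="sanity band"):
        BodyState.from_vector(y, 15).check()
    y2 = random_state_generator(4)
    y2[0] = np.nan
    with pytest.raises(FloatingPointError):
        BodyState.from_vector(y2, 15).check()


# --------------------------------------------------------------------------
# assembled RHS vs the independent scalar oracle (2-segment toy body)

def _toy_controls(rng, body):
    n = len(body["names"])
    flows = np.array([rng.uniform(body["m_min"][j], body["m_max"][j])
                      for j in range(n)])
    sweat = float(rng.uniform(0.0, 0.8))
    a_sw = np.asarray(body["alpha_sw"])
    return ControlOutputs(
        skin_flow_cm3h=flows,
        sweat_total_kgh=sweat,
        sweat_sector_kgh=sweat * a_sw[:, None] / 4.0 * np.ones((1, 4)),
        shiver_w=rng.uniform(0.0, 5.0, n),
        metabolic_multiplier=float(rng.uniform(1.0, 1.2)),
        Wrms=0.0, Clds=0.0, D=0.0, dHR=0.0)


def test_assembled_rhs_matches_scalar_oracle(toy_pair):
    model, body = toy_pair
    env = make_toy_env()
    renv = toy_resolved_env(env, body)
    rng = np.random.default_rng(12345)
    for _ in range(100):
        y = random_state_generator(int(rng.integers(0, 2**31)), n_segments=2)
        controls = _toy_controls(rng, body)
        prod = assemble_rhs(model, y, renv, controls)
        orac = scalar_rhs_oracle(body, y, env, {
            "skin_flow_cm3h": controls.skin_flow_cm3h,
            "sweat_total_kgh": controls.sweat_total_kgh,
            "shiver_w": controls.shiver_w,
            "mult": controls.metabolic_multiplier})
        np.testing.assert_allclose(prod, orac, rtol=1e-12, atol=1e-12)


def test_oracle_isothermal_state_gives_zero_passive_terms(toy_pair):
    """Isothermal body in an equally warm saturated-pressure-matched
    environment: every exchange term vanishes; only metabolism remains."""
    model, body = toy_pair
    env = make_toy_env()
    T0 = 36.0
    env["T_air"] = np.full((2, 4), T0)
    env["T_mrt"] = T0
    env["panel_T_r"] = T0
    # saturated air at skin temperature: zero evaporative capacity
    from oracles import _antoine
    env["P_air"] = np.full((2, 4), _antoine(T0))
    renv = toy_resolved_env(env, body)
    n = 2
    y = np.concatenate([np.full(7 * n, T0), [0.0]])
    controls = ControlOutputs(
        skin_flow_cm3h=np.zeros(n), sweat_total_kgh=0.0,
        sweat_sector_kgh=np.zeros((n, 4)), shiver_w=np.zeros(n),
        metabolic_multiplier=1.0, Wrms=0.0, Clds=0.0, D=0.0, dHR=0.0)
    dy = assemble_rhs(model, y, renv, controls, metabolism_enabled=False)
    # RES is zero too: disable respiration for the pure-equilibrium check
    renv.respiration_enabled = False
    dy = assemble_rhs(model, y, renv, controls, metabolism_enabled=False)
    np.testing.assert_allclose(dy, 0.0, atol=1e-14)


def test_perturbation_propagates_only_to_coupled_nodes(toy_pair):
    """Perturbing one skin sector changes only that sector, its ring
    neighbours, its segment core and (via perfusion return) its vein."""
    model, body = toy_pair
    env = make_toy_env()
    renv = toy_resolved_env(env, body)
    rng = np.random.default_rng(7)
    controls = _toy_controls(rng, body)
    n = 2
    y = np.concatenate([np.full(7 * n, 35.0), [0.0]])
    base = assemble_rhs(model, y, renv, controls)
    y2 = y.copy()
    y2[3 * n + 4 * 1 + 2] += 0.5       # limb skin, posterior sector
    pert = assemble_rhs(model, y2, renv, controls)
    changed = np.nonzero(np.abs(pert - base) > 1e-15)[0]
    # limb core (1), limb vein (2n+1), limb skin ring (3n+4..3n+7)
    allowed = {1, 2 * n + 1, 3 * n + 4, 3 * n + 5, 3 * n + 6, 3 * n + 7}
    assert set(changed) <= allowed


# --------------------------------------------------------------------------
# conservation properties of the full default body

def _adiabatic_env(n):
    from bioheatsim.environment_exchange import ResolvedEnvironment
    return ResolvedEnvironment(
        T_air=np.full((n, 4), 29.0), P_air=np.full((n, 4), 2.0),
        T_mrt=29.0, h_c=3.0, h_r=4.7, h_e=49.5, rad2_terms=[],
        panel_F_total=np.zeros((n, 4)),
        f_dry=np.ones(n), f_evap=np.ones(n), T_air_mean=29.0,
        exchange_enabled=False, respiration_enabled=False)


def test_internal_flows_conserve_enthalpy(default_model):
    """Adiabatic, metabolism-free body: Σ C·dT/dt = 0 for any state.

    Exercises the antisymmetry of every internal flow (conduction,
    perfusion, vessel convection, tree advection with heart closure)."""
    model = default_model
    env = _adiabatic_env(model.n)
    for seed in range(20):
        y = random_state_generator(seed)
        controls = model.controls(y, env, metabolism_enabled=False)
        dy = assemble_rhs(model, y, env, controls, metabolism_enabled=False)
        power = float(model.C_nodes @ dy[:7 * model.n])
        assert abs(power) < 1e-8   # W; internal flows are O(100 W)


def test_uniform_environment_preserves_sector_symmetry(default_model,
                                                       neutral_env):
    """A sector-symmetric state has a sector-symmetric derivative."""
    model = default_model
    rng = np.random.default_rng(11)
    y = np.empty(7 * model.n + 1)
    y[0:model.n] = rng.uniform(36.0, 38.0, model.n)
    y[model.n:3 * model.n] = rng.uniform(35.0, 37.0, 2 * model.n)
    seg_T = rng.uniform(31.0, 36.0, model.n)
    y[3 * model.n:7 * model.n] = np.repeat(seg_T, 4)
    y[-1] = 0.0
    controls = model.controls(y, neutral_env)
    dy = assemble_rhs(model, y, neutral_env, controls)
    dsk = dy[3 * model.n:7 * model.n].reshape(model.n, 4)
    assert float(np.max(dsk.max(1) - dsk.min(1))) == 0.0
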
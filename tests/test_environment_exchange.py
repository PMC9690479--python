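"""Boundary exchange terms, clothing, view-factor geometry."""

import numpy as np
import pytest

from bioheatsim.environment_exchange import (
    Panel, Stage, _Strip, apply_clothing, convective_loss, element_view_factor,
    evaporative_loss, radiative_loss, rect_view_factor,
    saturation_vapor_pressure, view_factor, wettedness_from_demand)

from oracles import (buck_saturation_pressure, dA_to_rect_quadrature,
                     parallel_rect_to_rect)


# --------------------------------------------------------------------------
# saturation pressure

@pytest.mark.parametrize("T", [25.0, 30.0, 34.0, 37.0, 41.0, 45.0])
def test_saturation_pressure_matches_independent_formula(T):
    # Antoine vs Buck agree to ~1 % over the physiological range
    assert saturation_vapor_pressure(T) == pytest.approx(
        buck_saturation_pressure(T), rel=0.015)


# --------------------------------------------------------------------------
# convection

def test_convective_loss_examples():
    assert convective_loss(34.0, 34.0, 0.035, 3.0) == 0.0
    assert convective_loss(44.0, 34.0, 0.035, 3.0) == pytest.approx(1.05)
    assert convective_loss(30.0, 40.0, 0.035, 3.0) == pytest.approx(-1.05)


# --------------------------------------------------------------------------
# evaporation

def test_evaporative_loss_balances_at_equal_pressure():
    T_sk = 35.0
    p = saturation_vapor_pressure(T_sk)
    assert evaporative_loss(T_sk, p, 1.0, 0.05, 16.5) == 0.0


def test_evaporative_loss_fully_wet_skin():
    # w=1, T_sk=35 °C: EVA = A·h_e·(P_sat(35) − 2) ≈ 2.99 W
    got = evaporative_loss(35.0, 2.0, 1.0, 0.05, 16.5)
    expected = 0.05 * 16.5 * (saturation_vapor_pressure(35.0) - 2.0)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(2.99, abs=0.05)


def test_evaporative_loss_floored_in_humid_air():
    assert evaporative_loss(32.0, 6.0, 0.06, 0.05, 16.5) == 0.0


def test_evaporative_loss_rejects_bad_wettedness():
    with pytest.raises(ValueError):
        evaporative_loss(35.0, 2.0, 1.2, 0.05, 16.5)
    with pytest.raises(ValueError):
        evaporative_loss(35.0, 2.0, -0.1, 0.05, 16.5)


def test_wettedness_clamps_to_physical_range():
    assert wettedness_from_demand(0.0, 10.0) == pytest.approx(0.06)
    assert wettedness_from_demand(5.0, 10.0) == pytest.approx(0.06 + 0.94 * 0.5)
    assert wettedness_from_demand(50.0, 10.0) == pytest.approx(1.0)
    assert wettedness_from_demand(5.0, 0.0) == pytest.approx(0.06)


# --------------------------------------------------------------------------
# radiation

def test_radiative_loss_vanishes_at_equilibrium():
    assert radiative_loss(30.0, 30.0, [], 0.05, 4.7) == 0.0
    # panel and MRT both at skin temperature: both parts vanish
    assert radiative_loss(30.0, 30.0, [(0.6, 30.0)], 0.05, 4.7) == \
        pytest.approx(0.0, abs=1e-14)


def test_radiative_panel_term_linear_in_view_factor():
    # with T_mrt = T_sk the MRT part is zero regardless of its weighting
    r1 = radiative_loss(33.0, 33.0, [(0.2, 60.0)], 0.05, 4.7)
    r2 = radiative_loss(33.0, 33.0, [(0.4, 60.0)], 0.05, 4.7)
    assert r2 == pytest.approx(2.0 * r1, rel=1e-12)
    assert r1 < 0.0    # hot panel is a gain


def test_radiative_hot_panel_heats_only_facing_sector():
    facing = radiative_loss(33.0, 20.0, [(0.7, 70.0)], 0.05, 4.7)
    opposite = radiative_loss(33.0, 20.0, [(0.0, 70.0)], 0.05, 4.7)
    assert facing < opposite   # panel turns a loss into a gain
    assert opposite == pytest.approx(0.05 * 4.7 * 13.0, rel=1e-12)


# --------------------------------------------------------------------------
# clothing

def test_clothing_identity_limit_and_monotonicity():
    dry, evap = apply_clothing(10.0, 5.0, 0.0, 0.0, 3.0, 4.7, 49.5)
    assert (dry, evap) == (10.0, 5.0)
    dry_inf, _ = apply_clothing(10.0, 5.0, 1e9, 0.0, 3.0, 4.7, 49.5)
    assert dry_inf == pytest.approx(0.0, abs=1e-6)
    last = 10.0
    for i_cl in (0.05, 0.1, 0.2, 0.4):
        dry, _ = apply_clothing(10.0, 5.0, i_cl, 0.0, 3.0, 4.7, 49.5)
        assert 0.0 < dry < last
        last = dry


# --------------------------------------------------------------------------
# view factors

def _panel_front(width, height, distance, lateral=0.0, base_z=None):
    base = -height / 2.0 if base_z is None else base_z
    return Panel(T_r=50.0, width=width, height=height, distance=distance,
                 azimuth_deg=0.0, base_z=base, lateral_offset=lateral)


def test_element_view_factor_matches_quadrature_oracle():
    p = np.zeros(3)
    cases = [
        (np.array([1.0, 0, 0]), _panel_front(2.0, 2.0, 0.5)),        # facing
        (np.array([0.0, 1, 0]), _panel_front(2.0, 2.0, 0.5)),        # sideways
        (np.array([1.0, 0, 0]), _panel_front(1.0, 2.5, 0.8, lateral=0.7)),
    ]
    for normal, panel in cases:
        got = element_view_factor(p, normal, panel.corners())
        ref = dA_to_rect_quadrature(p, normal, panel.corners())
        assert got == pytest.approx(ref, abs=1e-6)


def test_element_view_factor_enclosure_limit():
    # huge panel very close, directly facing: F → 1
    F = element_view_factor(np.zeros(3), np.array([1.0, 0, 0]),
                            _panel_front(2000.0, 2000.0, 1e-3).corners())
    assert F == pytest.approx(1.0, abs=1e-4)


def test_element_view_factor_behind_is_zero():
    F = element_view_factor(np.zeros(3), np.array([-1.0, 0, 0]),
                            _panel_front(2.0, 2.0, 0.5).corners())
    assert F == 0.0


def test_view_factor_decays_with_distance():
    kw = dict(sector_azimuth_deg=0.0, center_z=1.0, length=0.3, radius=0.05)
    F = [view_factor(Panel(T_r=50, width=1.0, height=1.0, distance=d,
                           azimuth_deg=0.0, base_z=0.5), **kw)
         for d in (0.5, 1.0, 2.0, 8.0)]
    assert all(a > b for a, b in zip(F, F[1:]))
    assert F[-1] < 0.01


def test_view_factor_degenerate_panel_is_zero():
    F = view_factor(Panel(T_r=50, width=0.0, height=2.0, distance=0.5),
                    sector_azimuth_deg=90.0, center_z=1.0, length=0.3,
                    radius=0.05)
    assert F == 0.0


def test_view_factor_additive_over_panel_split():
    """F(whole panel) = F(left half) + F(right half)."""
    kw = dict(sector_azimuth_deg=0.0, center_z=1.2, length=0.3, radius=0.05)
    whole = view_factor(_panel_front(2.0, 2.5, 0.5, base_z=0.0), **kw)
    left = view_factor(_panel_front(1.0, 2.5, 0.5, lateral=-0.5, base_z=0.0),
                       **kw)
    right = view_factor(_panel_front(1.0, 2.5, 0.5, lateral=0.5, base_z=0.0),
                        **kw)
    assert left + right == pytest.approx(whole, abs=1e-6)


def test_parallel_squares_benchmark():
    """Two directly opposed unit squares at unit distance: F ≈ 0.19982."""
    ref = parallel_rect_to_rect(1.0, 1.0, 1.0, 1.0, 1.0, n=256)
    assert ref == pytest.approx(0.19982, abs=1e-4)
    strip = _Strip(center=np.zeros(3), normal=np.array([1.0, 0, 0]),
                   width=1.0, height=1.0)
    got = rect_view_factor(strip, _panel_front(1.0, 1.0, 1.0).corners(),
                           nw=48, nh=48)
    assert got == pytest.approx(ref, abs=2e-4)


def test_view_factor_reciprocity_two_surface_enclosure():
    """A₁F₁₂ = A₂F₂₁ for a small strip facing a larger panel."""
    w1, h1 = 0.4, 0.6
    w2, h2 = 1.5, 2.0
    d = 0.8
    strip1 = _Strip(center=np.zeros(3), normal=np.array([1.0, 0, 0]),
                    width=w1, height=h1)
    F12 = rect_view_factor(strip1, _panel_front(w2, h2, d).corners(),
                           nw=64, nh=64)
    # surface 2 viewed back at surface 1: swap roles
    strip2 = _Strip(center=np.array([d, 0.0, 0.0]),
                    normal=np.array([-1.0, 0, 0]), width=w2, height=h2)
    corners1 = np.array([
        [0.0, w1 / 2, -h1 / 2], [0.0, -w1 / 2, -h1 / 2],
        [0.0, -w1 / 2, h1 / 2], [0.0, w1 / 2, h1 / 2]])
    F21 = rect_view_factor(strip2, corners1, nw=128, nh=128)
    assert w1 * h1 * F12 == pytest.approx(w2 * h2 * F21, abs=1e-5)


# --------------------------------------------------------------------------
# stage validation

def test_stage_validation_errors():
    with pytest.raises(ValueError, match="duration"):
        Stage(duration=0.0, T_air=29.0, rh=0.5).validate()
    with pytest.raises(ValueError, match="P_air or rh"):
        Stage(duration=60.0, T_air=29.0).validate()
    with pytest.raises(ValueError, match="h_c"):
        Stage(duration=60.0, T_air=29.0, rh=0.5, h_c=-1.0).validate()
    with pytest.raises(ValueError, match="distance"):
        Stage(duration=60.0, T_air=29.0, rh=0.5,
              panels=[Panel(T_r=50.0, width=1, height=1,
                            distance=0.0)]).validate()
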
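"""Packaged validation scenarios.

Two staged exposure protocols from the human heat-stress literature ship as
ready-to-run scenarios:

``uniform-fourstage``
    Resting, nearly unclothed subjects (shorts only) alternating between a
    neutral and a hot uniform chamber: 30 min at 29 °C, 30 min at 45 °C,
    30 min at 29 °C, 30 min at 45 °C.  Chamber humidity is not part of the
    protocol record; a moderate 40 % RH is assumed.

``fanger-warmwall``
    Seated subjects in standard KSU uniforms 0.5 m from a heated wall.  One
    unheated hour at 23 °C, then the wall is stepped every 30 min through
    32.6, 42, 51.6, 61.1 and 70.1 °C while the air temperature is lowered to
    21.9, 20.7, 19.3, 17.9 and 16.7 °C to hold the operative temperature
    steady.  The wall is modelled as a 2 m × 2.5 m vertical panel on the
    body's left side, so the left-arm exterior sector faces it directly.
"""

from __future__ import annotations

from .engine import Scenario
from .environment_exchange import ClothingSpec, EnvironmentSpec, Panel, Stage

__all__ = ["FIXTURE_NAMES", "uniform_fourstage", "fanger_warmwall", "get_fixture"]

#: KSU-uniform intrinsic insulation, m²K/W (≈ 0.6 clo over trunk and limbs).
_KSU_ICL = 0.093
#: Evaporative resistance of the same layer, m²kPa/W.
_KSU_RECL = 0.015

_KSU_SEGMENTS = ("chest", "abdomen", "left_upper_arm", "right_upper_arm",
                 "left_forearm", "right_forearm", "left_thigh", "right_thigh",
                 "left_calf", "right_calf")


def uniform_fourstage(dt: float = 1.0, output_every: float = 60.0) -> Scenario:
    """The 29/45/29/45 °C four-stage uniform exposure (120 min)."""
    stages = [Stage(duration=1800.0, T_air=T, rh=0.40) for T in
              (29.0, 45.0, 29.0, 45.0)]
    clothing = ClothingSpec(
        i_cl={"abdomen": 0.04, "left_thigh": 0.04, "right_thigh": 0.04},
        r_ecl={"abdomen": 0.006, "left_thigh": 0.006, "right_thigh": 0.006})
    return Scenario(name="uniform-fourstage",
                    environment=EnvironmentSpec(stages=stages),
                    clothing=clothing, dt=dt, output_every=output_every)


#: (wall temperature, air temperature) °C of the heated half-hour stages.
FANGER_WALL_STAGES = ((32.6, 21.9), (42.0, 20.7), (51.6, 19.3),
                      (61.1, 17.9), (70.1, 16.7))


def fanger_warmwall(dt: float = 1.0, output_every: float = 60.0) -> Scenario:
    """The asymmetric warm-wall protocol (60 min neutral + 5 × 30 min)."""
    def wall(t_r: float) -> Panel:
        return Panel(T_r=t_r, width=2.0, height=2.5, distance=0.5,
                     azimuth_deg=90.0, base_z=0.0)

    stages = [Stage(duration=3600.0, T_air=23.0, rh=0.40)]
    for t_wall, t_air in FANGER_WALL_STAGES:
        stages.append(Stage(duration=1800.0, T_air=t_air, rh=0.40,
                            panels=[wall(t_wall)]))
    clothing = ClothingSpec(
        i_cl={s: _KSU_ICL for s in _KSU_SEGMENTS} | {"left_foot": 0.06,
                                                     "right_foot": 0.06},
        r_ecl={s: _KSU_RECL for s in _KSU_SEGMENTS} | {"left_foot": 0.010,
                                                       "right_foot": 0.010})
    return Scenario(name="fanger-warmwall",
                    environment=EnvironmentSpec(stages=stages),
                    clothing=clothing, dt=dt, output_every=output_every)


FIXTURE_NAMES = ("uniform-fourstage", "fanger-warmwall")


def get_fixture(name: str, **kwargs) -> Scenario:
    """Fetch a packaged scenario by name."""
    builders = {"uniform-fourstage": uniform_fourstage,
                "fanger-warmwall": fanger_warmwall}
    try:
        return builders[name](**kwargs)
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {', '.join(FIXTURE_NAMES)}") from None
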
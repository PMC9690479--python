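"""Scenario files: pydantic schema, YAML loading and serialization.

Scenario files are YAML (or JSON) documents validated against the pydantic
models below; unknown keys are rejected.  Units: SI throughout with
temperatures in °C, vapor pressures in kPa, skin blood flow in cm³/h.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import Scenario
from .environment_exchange import (ClothingSpec, EnvironmentSpec, Panel, Stage)

__all__ = [
    "ScenarioModel",
    "ManifestModel",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "scenario_to_yaml",
    "validate_manifest",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PanelModel(_Strict):
    t_r: float = Field(description="panel surface temperature, °C")
    width: float = 2.0
    height: float = 2.5
    distance: float
    azimuth_deg: float = 90.0
    base_z: float = 0.0
    lateral_offset: float = 0.0
    emissivity: float = 0.95


class StageModel(_Strict):
    duration: float = Field(gt=0.0, description="stage duration, s")
    t_air: float | list[float]
    p_air: float | list[float] | None = None
    rh: float | None = Field(default=None, ge=0.0, le=1.0)
    t_mrt: float | None = None
    h_c: float = 3.0
    h_r: float = 4.7
    h_e: float | None = None
    panels: list[PanelModel] = []

    @model_validator(mode="after")
    def _humidity(self):
        if self.p_air is None and self.rh is None:
            raise ValueError("stage needs p_air or rh")
        return self


class ClothingModel(_Strict):
    i_cl: dict[str, float] = {}
    r_ecl: dict[str, float] = {}


class IntegratorModel(_Strict):
    dt: float = 1.0
    output_every: float = 60.0


class ScenarioModel(_Strict):
    name: str = "scenario"
    body: dict[str, dict[str, float]] = {}
    active_system: dict[str, float] = {}
    clothing: ClothingModel = ClothingModel()
    stages: list[StageModel]
    integrator: IntegratorModel = IntegratorModel()
    metabolism_enabled: bool = True
    exchange_enabled: bool = True
    respiration_enabled: bool = True


class ManifestModel(_Strict):
    """Schema of the run manifest written next to every trajectory."""

    package: str
    version: str
    scenario: ScenarioModel
    invariants: dict[str, float | int | bool]


def _stage_from_model(sm: StageModel) -> Stage:
    return Stage(
        duration=sm.duration, T_air=sm.t_air, P_air=sm.p_air, rh=sm.rh,
        T_mrt=sm.t_mrt, h_c=sm.h_c, h_r=sm.h_r, h_e=sm.h_e,
        panels=[Panel(T_r=p.t_r, width=p.width, height=p.height,
                      distance=p.distance, azimuth_deg=p.azimuth_deg,
                      base_z=p.base_z, lateral_offset=p.lateral_offset,
                      emissivity=p.emissivity) for p in sm.panels])


def scenario_from_dict(data: dict[str, Any]) -> Scenario:
    sm = ScenarioModel.model_validate(data)
    return Scenario(
        name=sm.name,
        environment=EnvironmentSpec(stages=[_stage_from_model(s)
                                            for s in sm.stages]),
        body_overrides=sm.body,
        active_overrides=sm.active_system,
        clothing=ClothingSpec(i_cl=dict(sm.clothing.i_cl),
                              r_ecl=dict(sm.clothing.r_ecl)),
        dt=sm.integrator.dt,
        output_every=sm.integrator.output_every,
        metabolism_enabled=sm.metabolism_enabled,
        exchange_enabled=sm.exchange_enabled,
        respiration_enabled=sm.respiration_enabled,
    )


def scenario_to_dict(sc: Scenario) -> dict[str, Any]:
    stages = []
    for st in sc.environment.stages:
        stages.append({
            "duration": st.duration, "t_air": st.T_air, "p_air": st.P_air,
            "rh": st.rh, "t_mrt": st.T_mrt, "h_c": st.h_c, "h_r": st.h_r,
            "h_e": st.h_e,
            "panels": [{"t_r": p.T_r, "width": p.width, "height": p.height,
                        "distance": p.distance, "azimuth_deg": p.azimuth_deg,
                        "base_z": p.base_z, "lateral_offset": p.lateral_offset,
                        "emissivity": p.emissivity} for p in st.panels]})
    return {
        "name": sc.name,
        "body": sc.body_overrides,
        "active_system": sc.active_overrides,
        "clothing": {"i_cl": sc.clothing.i_cl, "r_ecl": sc.clothing.r_ecl},
        "stages": stages,
        "integrator": {"dt": sc.dt, "output_every": sc.output_every},
        "metabolism_enabled": sc.metabolism_enabled,
        "exchange_enabled": sc.exchange_enabled,
        "respiration_enabled": sc.respiration_enabled,
    }


def _clean_nones(obj):
    if isinstance(obj, dict):
        return {k: _clean_nones(v) for k, v in obj.items() if v is not None}
    if isinstance(obj, list):
        return [_clean_nones(v) for v in obj]
    return obj


def scenario_to_yaml(sc: Scenario) -> str:
    return yaml.safe_dump(_clean_nones(scenario_to_dict(sc)), sort_keys=False)


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a YAML/JSON scenario file."""
    data = yaml.safe_load(Path(path).read_text())
    return scenario_from_dict(data)


def validate_manifest(data: dict[str, Any]) -> ManifestModel:
    """Validate a run manifest against the shipped schema."""
    return ManifestModel.model_validate(data)
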
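"""Scenario execution: stage resolution, time integration and output.

A :class:`Scenario` bundles body/clothing overrides, a staged environment,
controller settings and integrator options.  :func:`run` pre-equilibrates
the body in the first stage's environment (unless an initial state is
given), integrates the 105-node system with a fixed-step classical
Runge–Kutta scheme (default Δt = 1 s; the stiffest vessel nodes have time
constants of a few seconds, comfortably inside the stability region), and
samples the trajectory on a regular output grid.  The state is continuous
across stage boundaries while the boundary conditions switch stepwise.

Runs are deterministic: identical scenarios produce bit-identical results
on one platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from . import __version__ as _pkg_version
from .body_parameters import (SECTOR_NAMES, ThermoregParams, apply_overrides,
                              load_default_body, validate_parameters)
from .environment_exchange import (ClothingSpec, EnvironmentSpec,
                                   ResolvedEnvironment, Stage,
                                   saturation_vapor_pressure, view_factor)
from .passive_body import BodyModel, BodyState, assemble_rhs, compute_heat_flows

__all__ = [
    "Scenario",
    "SimulationResult",
    "SimulationError",
    "EquilibrationError",
    "build_model",
    "resolve_environment",
    "equilibrate",
    "run",
    "write_result",
]

#: Vertical centre (m above floor) of each segment for radiant geometry.
_CENTER_Z = {
    "head": 1.60, "chest": 1.25, "abdomen": 0.95,
    "upper_arm": 1.20, "forearm": 0.95, "hand": 0.75,
    "thigh": 0.65, "calf": 0.25, "foot": 0.05,
}


class SimulationError(RuntimeError):
    """A state invariant was violated during integration."""


class EquilibrationError(RuntimeError):
    """The neutral steady state could not be reached."""


@dataclass
class Scenario:
    """Full description of one simulation."""

    environment: EnvironmentSpec
    name: str = "scenario"
    body_overrides: dict = field(default_factory=dict)
    active_overrides: dict = field(default_factory=dict)
    clothing: ClothingSpec = field(default_factory=ClothingSpec)
    dt: float = 1.0
    output_every: float = 60.0
    metabolism_enabled: bool = True
    exchange_enabled: bool = True
    respiration_enabled: bool = True
    initial_state: BodyState | None = None

    def validate(self) -> None:
        self.environment.validate()
        self.clothing.validate()
        if not self.dt > 0.0:
            raise ValueError("dt must be positive")
        if self.output_every < self.dt:
            raise ValueError("output cadence must be ≥ dt")
        if abs(self.output_every / self.dt - round(self.output_every / self.dt)) > 1e-9:
            raise ValueError("output cadence must be a multiple of dt")
        if self.output_every > self.environment.total_duration:
            raise ValueError("output cadence exceeds total duration")


def build_model(scenario: Scenario) -> BodyModel:
    """Instantiate the body model for a scenario (defaults + overrides)."""
    segments, thermo = load_default_body()
    segments, thermo = apply_overrides(segments, thermo, scenario.body_overrides)
    if scenario.active_overrides:
        valid = {f.name for f in dataclasses.fields(ThermoregParams)}
        bad = set(scenario.active_overrides) - valid
        if bad:
            raise ValueError(f"unknown active_system settings: {sorted(bad)}")
        thermo = dataclasses.replace(thermo, **scenario.active_overrides)
    validate_parameters(segments, thermo, strict=True)
    return BodyModel(segments, thermo, clothing=scenario.clothing)


def _segment_geometry(model: BodyModel, j: int) -> tuple[float, float, float, dict]:
    """(center_z, length, radius, sector azimuths in deg) for segment j."""
    name = model.names[j]
    base = name.removeprefix("left_").removeprefix("right_")
    seg = model.segments[j]
    if name.startswith("right_"):
        az = {"anterior": 0.0, "exterior": -90.0, "posterior": 180.0,
              "inferior": 90.0}
    else:  # left-side and central segments: exterior faces the body's left
        az = {"anterior": 0.0, "exterior": 90.0, "posterior": 180.0,
              "inferior": -90.0}
    return _CENTER_Z.get(base, 1.0), seg.L_n, seg.r, az


def resolve_environment(model: BodyModel, stage: Stage,
                        exchange_enabled: bool = True,
                        respiration_enabled: bool = True) -> ResolvedEnvironment:
    """Resolve a stage onto a body: broadcast fields, view factors, clothing."""
    n = model.n

    def broadcast(v):
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full((n, 4), float(arr))
        if arr.shape == (4,):
            return np.tile(arr, (n, 1))
        if arr.shape == (n, 4):
            return arr.copy()
        raise ValueError("per-sector fields must be scalar, length-4 or (n,4)")

    T_air = broadcast(stage.T_air)
    if stage.P_air is not None:
        P_air = broadcast(stage.P_air)
    else:
        P_air = stage.rh * saturation_vapor_pressure(T_air)
    T_mrt = float(stage.T_mrt) if stage.T_mrt is not None else float(T_air.mean())
    h_e = stage.h_e if stage.h_e is not None else 16.5 * stage.h_c

    rad2_terms = []
    F_total = np.zeros((n, 4))
    for panel in stage.panels:
        coeff = np.zeros((n, 4))
        for j in range(n):
            cz, L, r, az = _segment_geometry(model, j)
            for i, sec in enumerate(SECTOR_NAMES):
                F = view_factor(panel, sector_azimuth_deg=az[sec],
                                center_z=cz, length=L, radius=r)
                F_total[j, i] += F
                coeff[j, i] = 5.670374419e-8 * model.epsilon[j] \
                    * panel.emissivity * F
        rad2_terms.append((coeff, panel.T_r))
    F_total = np.minimum(F_total, 1.0)

    f_dry, f_evap = model.clothing_factors(stage.h_c, stage.h_r, h_e)
    return ResolvedEnvironment(
        T_air=T_air, P_air=P_air, T_mrt=T_mrt,
        h_c=stage.h_c, h_r=stage.h_r, h_e=h_e,
        rad2_terms=rad2_terms, panel_F_total=F_total,
        f_dry=f_dry, f_evap=f_evap,
        T_air_mean=float(T_air.mean()),
        exchange_enabled=exchange_enabled,
        respiration_enabled=respiration_enabled)


def _rhs(model: BodyModel, y: np.ndarray, env: ResolvedEnvironment,
         metabolism: bool) -> np.ndarray:
    controls = model.controls(y, env, metabolism_enabled=metabolism)
    return assemble_rhs(model, y, env, controls, metabolism_enabled=metabolism)


def _rk4_step(model, y, env, dt, metabolism):
    k1 = _rhs(model, y, env, metabolism)
    k2 = _rhs(model, y + 0.5 * dt * k1, env, metabolism)
    k3 = _rhs(model, y + 0.5 * dt * k2, env, metabolism)
    k4 = _rhs(model, y + dt * k3, env, metabolism)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _default_guess(model: BodyModel) -> np.ndarray:
    n = model.n
    y = np.empty(7 * n + 1)
    y[0:n] = 36.8
    y[n:3 * n] = 36.5
    y[3 * n:7 * n] = 33.8
    y[7 * n] = 0.0
    return y


def _is_angularly_uniform(env: ResolvedEnvironment) -> bool:
    return (not env.rad2_terms
            and np.all(env.T_air == env.T_air[:, :1])
            and np.all(env.P_air == env.P_air[:, :1]))


def equilibrate(model: BodyModel, env: ResolvedEnvironment,
                tol: float = 1e-7, dt: float = 1.0,
                max_model_seconds: float = 1.0e4,
                metabolism_enabled: bool = True,
                y0: np.ndarray | None = None) -> BodyState:
    """Find the steady state of the body in a constant environment.

    The sweat accumulator is frozen at zero (a nonzero steady sweat rate
    would otherwise slowly drift the dehydration state).  In an angularly
    uniform environment the equilibrium is sector-symmetric and is solved
    directly on the reduced symmetric manifold (where the perfusion
    redistribution is smooth); otherwise the state is integrated toward
    equilibrium and polished with a Newton root solve.  Raises
    :class:`EquilibrationError` when ``max |dT/dt|`` cannot be brought below
    ``tol`` (K/s) within the model-time budget.
    """
    n = model.n
    n_temp = 7 * n
    y = _default_guess(model) if y0 is None else np.asarray(y0, dtype=float).copy()
    y[-1] = 0.0

    def full_resid(yy: np.ndarray) -> np.ndarray:
        return _rhs(model, yy, env, metabolism_enabled)[:n_temp]

    def finish(yy: np.ndarray) -> BodyState:
        state = BodyState.from_vector(yy, n)
        state.check()
        return state

    if _is_angularly_uniform(env):
        # Reduced symmetric system: one skin unknown per segment.  The
        # per-sector perfusion redistribution is non-smooth exactly on the
        # symmetric manifold, so Newton runs in the reduced space where it
        # takes the equal-split branch.
        def expand(x: np.ndarray) -> np.ndarray:
            yy = np.empty(n_temp + 1)
            yy[0:3 * n] = x[0:3 * n]
            yy[3 * n:7 * n] = np.repeat(x[3 * n:4 * n], 4)
            yy[-1] = 0.0
            return yy

        def f_red(x: np.ndarray) -> np.ndarray:
            dy = full_resid(expand(x))
            return np.concatenate([dy[0:3 * n], dy[3 * n:7 * n:4]])

        x0 = np.concatenate([y[0:3 * n], y[3 * n:7 * n:4]])
        sol = scipy.optimize.root(f_red, x0, method="hybr",
                                  options={"xtol": 1e-13})
        yy = expand(sol.x)
        resid = float(np.max(np.abs(full_resid(yy))))
        if resid < tol:
            return finish(yy)
        # fall through to integration from the best point found
        y = yy

    def f_full(x: np.ndarray) -> np.ndarray:
        return full_resid(np.concatenate([x, [0.0]]))

    elapsed = 0.0
    chunk = 2000.0
    while True:
        sol = scipy.optimize.root(f_full, y[:n_temp], method="hybr",
                                  options={"xtol": 1e-12})
        resid = float(np.max(np.abs(f_full(sol.x))))
        if resid < tol:
            y = np.concatenate([sol.x, [0.0]])
            return finish(y)
        if elapsed >= max_model_seconds:
            raise EquilibrationError(
                f"no steady state within {max_model_seconds:.0f} model-seconds "
                f"(residual {resid:.2e} K/s > tol {tol:.0e})")
        steps = int(round(min(chunk, max_model_seconds - elapsed) / dt))
        for _ in range(steps):
            y = _rk4_step(model, y, env, dt, metabolism_enabled)
            y[-1] = 0.0
        elapsed += steps * dt


@dataclass
class SimulationResult:
    """Sampled trajectory of a scenario run plus derived outputs."""

    model: BodyModel
    scenario: Scenario
    times: np.ndarray              # (nt,) s, strictly increasing
    states: np.ndarray             # (nt, 7n+1)
    stage_index: np.ndarray        # (nt,) which stage each sample belongs to
    environments: list[ResolvedEnvironment]

    @property
    def n_segments(self) -> int:
        return self.model.n

    def state(self, i: int) -> BodyState:
        return BodyState.from_vector(self.states[i], self.model.n,
                                     t=float(self.times[i]))

    @property
    def T_cr(self) -> np.ndarray:
        return self.states[:, 0:self.model.n]

    @property
    def T_sk(self) -> np.ndarray:
        n = self.model.n
        return self.states[:, 3 * n:7 * n].reshape(len(self.times), n, 4)

    @property
    def T_sk_segment_mean(self) -> np.ndarray:
        return self.T_sk.mean(axis=2)

    @property
    def T_sk_mean(self) -> np.ndarray:
        """Whole-body area-weighted mean skin temperature, °C."""
        w = self.model.A_sector
        return (self.T_sk * w[None, :, None]).sum(axis=(1, 2)) \
            / (4.0 * w.sum())

    def _controls_series(self):
        out = []
        for i, t in enumerate(self.times):
            env = self.environments[self.stage_index[i]]
            out.append(self.model.controls(
                self.states[i], env,
                metabolism_enabled=self.scenario.metabolism_enabled))
        return out

    @property
    def sweat_rate(self) -> np.ndarray:
        return np.array([c.sweat_total_kgh for c in self._controls_series()])

    @property
    def D(self) -> np.ndarray:
        m = self.model.thermo.body_mass_ref
        return 100.0 * self.states[:, -1] / m

    @property
    def dHR(self) -> np.ndarray:
        return 4.75 * self.D

    def fluxes(self, i: int):
        env = self.environments[self.stage_index[i]]
        controls = self.model.controls(
            self.states[i], env,
            metabolism_enabled=self.scenario.metabolism_enabled)
        return compute_heat_flows(self.model, self.states[i], env, controls)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: (time_s, segment, node, sector, value)."""
        n = self.model.n
        rows = []
        names = self.model.names
        for i, t in enumerate(self.times):
            y = self.states[i]
            for j, nm in enumerate(names):
                rows.append((t, nm, "core", "", y[j]))
                rows.append((t, nm, "artery", "", y[n + j]))
                rows.append((t, nm, "vein", "", y[2 * n + j]))
                for k, sec in enumerate(SECTOR_NAMES):
                    rows.append((t, nm, "skin", sec, y[3 * n + 4 * j + k]))
            rows.append((t, "body", "sweat_cumulative_kg", "", y[-1]))
        df = pd.DataFrame(rows, columns=["time_s", "segment", "node",
                                         "sector", "value"])
        return df


def run(scenario: Scenario) -> SimulationResult:
    """Execute a staged scenario and return the sampled trajectory."""
    scenario.validate()
    model = build_model(scenario)
    envs = [resolve_environment(model, st, scenario.exchange_enabled,
                                scenario.respiration_enabled)
            for st in scenario.environment.stages]

    if scenario.initial_state is not None:
        y = scenario.initial_state.to_vector()
    else:
        y = equilibrate(model, envs[0],
                        metabolism_enabled=scenario.metabolism_enabled
                        ).to_vector()

    dt = scenario.dt
    rec_stride = int(round(scenario.output_every / dt))
    times = [0.0]
    states = [y.copy()]
    stage_idx = [0]
    t = 0.0
    gstep = 0
    for s_i, (env, stage) in enumerate(zip(envs, scenario.environment.stages)):
        nsteps = int(round(stage.duration / dt))
        for _ in range(nsteps):
            y = _rk4_step(model, y, env, dt, scenario.metabolism_enabled)
            t += dt
            gstep += 1
            if gstep % rec_stride == 0:
                state = BodyState.from_vector(y, model.n, t=t)
                try:
                    state.check()
                except (ValueError, FloatingPointError) as exc:
                    raise SimulationError(
                        f"invariant violation at t={t:.0f} s: {exc}") from exc
                times.append(t)
                states.append(y.copy())
                stage_idx.append(s_i)
    return SimulationResult(model=model, scenario=scenario,
                            times=np.asarray(times), states=np.asarray(states),
                            stage_index=np.asarray(stage_idx),
                            environments=envs)


def write_result(result: SimulationResult, path: str | Path,
                 fmt: str = "csv") -> list[Path]:
    """Write the trajectory and a run manifest under ``path``.

    ``csv`` produces a tidy long-format table that round-trips the sampled
    trajectory exactly; ``json`` nests the same records.  The manifest holds
    the resolved configuration, package version and an invariant summary.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    df = result.to_dataframe()
    written = []
    if fmt == "csv":
        traj = outdir / "trajectory.csv"
        # %.17g round-trips float64 exactly
        df.to_csv(traj, index=False, float_format="%.17g")
    elif fmt == "json":
        traj = outdir / "trajectory.json"
        traj.write_text(df.to_json(orient="records"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    written.append(traj)

    from .config import scenario_to_dict  # local import avoids a cycle
    temps = result.states[:, :-1]
    manifest = {
        "package": "bioheatsim",
        "version": _pkg_version,
        "scenario": scenario_to_dict(result.scenario),
        "invariants": {
            "n_samples": int(len(result.times)),
            "t_final_s": float(result.times[-1]),
            "temp_min_c": float(temps.min()),
            "temp_max_c": float(temps.max()),
            "all_finite": bool(np.all(np.isfinite(result.states))),
            "monotone_time": bool(np.all(np.diff(result.times) > 0)),
        },
    }
    man = outdir / "manifest.json"
    man.write_text(json.dumps(manifest, indent=2))
    written.append(man)
    return written
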
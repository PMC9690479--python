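"""Shared fixtures: default body, resolved environments, cached protocol runs."""

from __future__ import annotations

import numpy as np
import pytest

from bioheatsim import (BodyModel, load_default_body)
from bioheatsim.circulation import BloodNetwork
from bioheatsim.body_parameters import ThermoregParams, SegmentParameters
from bioheatsim.engine import equilibrate, resolve_environment, run
from bioheatsim.environment_exchange import ResolvedEnvironment
from bioheatsim.fixtures import fanger_warmwall, uniform_fourstage

from oracles import make_toy_body


@pytest.fixture(scope="session")
def default_body():
    return load_default_body()


@pytest.fixture(scope="session")
def default_model(default_body):
    segments, thermo = default_body
    return BodyModel(segments, thermo)


@pytest.fixture(scope="session")
def neutral_env(default_model):
    sc = uniform_fourstage()
    return resolve_environment(default_model, sc.environment.stages[0])


@pytest.fixture(scope="session")
def neutral_state(default_model, neutral_env):
    return equilibrate(default_model, neutral_env)


@pytest.fixture(scope="session")
def fourstage_result():
    return run(uniform_fourstage())


@pytest.fixture(scope="session")
def fourstage_result_dt2():
    return run(uniform_fourstage(dt=2.0))


@pytest.fixture(scope="session")
def warmwall_result():
    return run(fanger_warmwall())


@pytest.fixture()
def toy_pair():
    """The 2-segment toy body in both representations.

    Returns ``(model, body_dict)``: the production :class:`BodyModel` and the
    plain dict the scalar oracle consumes, built from one set of numbers.
    """
    body = make_toy_body()
    segments = [
        SegmentParameters(
            name=body["names"][j], A=body["A"][j], M_cr=body["M_cr"][j],
            M_sk=body["M_sk"][j], W_cr=body["W_cr"][j], C_cr=body["C_cr"][j],
            C_bl_a=body["C_a"][j], C_bl_v=body["C_v"][j],
            C_sk=body["C_sk"][j], K_cr_sk=body["K_cr_sk"][j],
            m_sk_basal=body["m_basal"][j], m_sk_min=body["m_min"][j],
            m_sk_max=body["m_max"][j], L_n=body["L_n"][j], r=body["r"][j],
            th_sk=body["th_sk"][j], K_sk=body["K_sk"][j],
            epsilon=body["eps"][j])
        for j in range(2)]
    thermo = ThermoregParams(
        T_sk0={"chest": 34.0, "limb": 34.0},
        alpha_sk={"chest": 0.5, "limb": 0.5},
        alpha_sh={"chest": 0.5, "limb": 0.5},
        alpha_sw={"chest": 0.5, "limb": 0.5},
        c_bl=body["c_bl"], blood_density=body["rho_bl"],
        core_perfusion_total=body["core_perfusion_total"])
    network = BloodNetwork(parent=np.array(body["parent"]), root=body["root"],
                           h_a=np.array(body["h_a"]),
                           h_v=np.array(body["h_v"]))
    from bioheatsim.environment_exchange import ClothingSpec
    clothing = ClothingSpec(
        i_cl={body["names"][j]: body["i_cl"][j] for j in range(2)},
        r_ecl={body["names"][j]: body["r_ecl"][j] for j in range(2)})
    model = BodyModel(segments, thermo, network=network, clothing=clothing)
    return model, body


def toy_resolved_env(env: dict, body: dict) -> ResolvedEnvironment:
    """Build the production environment container from the toy env dict."""
    import bioheatsim.environment_exchange as ee
    F = np.asarray(env["panel_F"], float)
    eps = np.asarray(body["eps"], float)
    coeff = ee.SIGMA_SB * eps[:, None] * env["panel_eps"] * F
    i_cl = np.asarray(body["i_cl"], float)
    r_ecl = np.asarray(body["r_ecl"], float)
    return ResolvedEnvironment(
        T_air=np.asarray(env["T_air"], float),
        P_air=np.asarray(env["P_air"], float),
        T_mrt=env["T_mrt"], h_c=env["h_c"], h_r=env["h_r"], h_e=env["h_e"],
        rad2_terms=[(coeff, env["panel_T_r"])],
        panel_F_total=F.copy(),
        f_dry=1.0 / (1.0 + (env["h_c"] + env["h_r"]) * i_cl),
        f_evap=1.0 / (1.0 + env["h_e"] * r_ecl),
        T_air_mean=float(np.mean(env["T_air"])))
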
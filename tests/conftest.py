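"""Shared fixtures.

The expensive artifacts — channel oracle solves and the paired analogue
pipeline runs — are session-scoped so the unit, property and acceptance
tests all measure the same computations.
"""

import numpy as np
import pytest

from graftflow.fixtures import (
    ANGIOPLASTY_INTERVAL,
    ANGIOPLASTY_VESSEL,
    control_config,
    occlusion_config,
)
from graftflow.meshing import channel_mesh
from graftflow.pipeline import run_case, run_intervention
from graftflow.solver import SolverConfig, solve_pulsatile
from graftflow.waveforms import FlowWaveform
from graftflow.womersley import FluidProperties

BLOOD = FluidProperties()  # rho 1060, mu 3.5e-3


@pytest.fixture(scope="session")
def steady_channel():
    """Steady Poiseuille flow in a straight channel at default resolution.

    Returns (mesh, history, half_width, mean_velocity, fluid).
    """
    a, L = 3e-3, 0.03
    mesh = channel_mesh(L, a, a / 8)
    u_mean = 0.1
    t = np.arange(64) / 64
    inflow = FlowWaveform(t=t, Q=np.full(64, u_mean * 2 * a), T=1.0)
    cfg = SolverConfig(
        fluid=BLOOD, dt=2e-3, cycles_max=8, backflow_beta=0.0,
        periodicity_tol=1e-3,
    )
    history = solve_pulsatile(mesh, inflow, {"OUT": 0.0}, cfg)
    return mesh, history, a, u_mean, BLOOD


@pytest.fixture(scope="session")
def oscillatory_channel():
    """Single-harmonic channel flow at two resolutions (coarse, default).

    Returns dict resolution -> (mesh, history, inflow); amplitudes are in
    the linear regime so the analytic oscillatory solution is the truth.
    """
    a, L, T = 2e-3, 0.02, 1.0
    q1 = 0.025 * 2 * a
    t = np.arange(128) / 128
    inflow = FlowWaveform(t=t, Q=q1 * np.cos(2 * np.pi * t), T=T)
    out = {}
    for res, dt in [(a / 4, 2e-3), (a / 8, 1e-3)]:
        mesh = channel_mesh(L, a, res)
        cfg = SolverConfig(
            fluid=BLOOD, dt=dt, cycles_max=12, backflow_beta=0.0,
            periodicity_tol=2e-4, n_store=50, cfl_target=0.5,
        )
        out[res] = (mesh, solve_pulsatile(mesh, inflow, {"OUT": 0.0}, cfg), inflow)
    return {"half_width": a, "length": L, "runs": out, "fluid": BLOOD}


@pytest.fixture(scope="session")
def control_result():
    return run_case(control_config(seed=1), label="control")


@pytest.fixture(scope="session")
def occlusion_result():
    return run_case(occlusion_config(seed=1), label="occlusion")


@pytest.fixture(scope="session")
def intervention_result(occlusion_result):
    return run_intervention(
        occlusion_config(seed=1),
        ANGIOPLASTY_VESSEL,
        ANGIOPLASTY_INTERVAL,
        baseline=occlusion_result,
    )
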
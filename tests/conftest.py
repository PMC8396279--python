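"""Shared fixtures: interaction tables, small systems, and the scaled-down
replication run reused by several acceptance checks."""

import numpy as np
import pytest

from brushmd.build import BoxSpec, Configuration
from brushmd.config import RunConfig
from brushmd.model import make_interaction_table


@pytest.fixture(scope="session")
def table_m1():
    return make_interaction_table("M1", eps_Ps=1.5, sigma_c=4.0, sigma_P=1.0)


@pytest.fixture(scope="session")
def table_m1a():
    return make_interaction_table("M1a", eps_Ps=3.0, sigma_c=4.0, sigma_P=1.0)


def two_bead(r, species, L=20.0, bonded=False):
    pos = np.array([[0.5 * L] * 3, [0.5 * L + r, 0.5 * L, 0.5 * L]])
    bonds = np.array([[0, 1]], dtype=np.int64) if bonded else np.zeros((0, 2), np.int64)
    return Configuration(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=np.array(species, dtype=np.int8),
        mobile=np.ones(2, dtype=bool),
        bonds=bonds,
        box=BoxSpec.cubic(L),
        spec={},
    )


@pytest.fixture(scope="session")
def scaled_run_config():
    """The scaled-down M1 replication state point: sigma_c=4, f=20, M=10,
    eps_Ps=1.5, rho0=0.01, L=30, 1e5 equilibration + 1e5 production."""
    return RunConfig(
        variant="M1",
        f=20,
        M=10,
        sigma_c=4.0,
        eps_Ps=1.5,
        L=30.0,
        rho0=[0.01],
        equilibration_steps=100_000,
        production_steps=100_000,
        sample_interval=200,
        seeds=[1, 2, 3],
    )


@pytest.fixture(scope="session")
def scaled_m1_runs(scaled_run_config):
    """Three replicate runs of the scaled-down M1 state point (shared:
    these back the peak-structure, thermostat and route-consistency
    acceptance checks)."""
    from brushmd.workflow import run_state_point

    return [
        run_state_point(scaled_run_config, scaled_run_config.rho0[0], seed)
        for seed in scaled_run_config.seeds
    ]
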
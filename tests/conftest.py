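"""Shared fixtures: one solved head model reused across the whole suite."""
import numpy as np
import pytest

from ocufield.evaluation import (ChannelSolver, run_mitigation_conditions,
                                 run_step1_separation_sweep,
                                 run_step2_intended_regions)
from ocufield.meshing import (HeadGeometryParams, generate_homogeneous_box,
                              generate_layered_head)
from ocufield.tissues import ConductivityTable, default_conductivities


@pytest.fixture(scope="session")
def head_params():
    return HeadGeometryParams()


@pytest.fixture(scope="session")
def head_mesh(head_params):
    return generate_layered_head(head_params)


@pytest.fixture(scope="session")
def head_solver(head_mesh):
    return ChannelSolver(head_mesh, default_conductivities())


@pytest.fixture(scope="session")
def step1_report(head_solver):
    return run_step1_separation_sweep(head_solver)


@pytest.fixture(scope="session")
def step2_report(head_solver):
    return run_step2_intended_regions(head_solver)


@pytest.fixture(scope="session")
def mitigation_report(head_solver):
    return run_mitigation_conditions(head_solver)


@pytest.fixture(scope="session")
def box_verification():
    from ocufield.oracles import run_box_verification
    return run_box_verification()


@pytest.fixture(scope="session")
def small_box():
    mesh = generate_homogeneous_box(100.0, 0.5, 10.0)
    table = ConductivityTable({"medium": 0.5})
    return mesh, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
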
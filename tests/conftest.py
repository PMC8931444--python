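"""Shared fixtures: small geometries and forward models reused across tests."""

import numpy as np
import pytest

from opus2g.forward import assemble_forward_model
from opus2g.geometry import TIRKernel, desk_geometry


@pytest.fixture(scope="session")
def mini_geometry():
    """Tiny geometry for fast unit tests (16 elements, 31x31 grid)."""
    return desk_geometry(n_elements=16, grid=31)


@pytest.fixture(scope="session")
def mini_model(mini_geometry):
    """Dual-SoS forward model with a delta TIR on the mini geometry."""
    return assemble_forward_model(mini_geometry, TIRKernel.delta(), "dual")


@pytest.fixture(scope="session")
def desk_model_dual():
    """Desk-scale dual-SoS model (64 elements, 101x101 grid, delta TIR)."""
    return assemble_forward_model(desk_geometry(), TIRKernel.delta(), "dual")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
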
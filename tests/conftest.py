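"""Shared fixtures: packaged reference objects and one small simulated scheme.

Expensive objects are module- or session-scoped so the numba kernels compile
once and simulations are reused across tests.
"""

import numpy as np
import pytest

from piptype import packaged_anchor, packaged_scheme
from piptype.simulate import SimulationConfig, generate_clade_scheme


@pytest.fixture(scope="session")
def anchor():
    return packaged_anchor()


@pytest.fixture(scope="session")
def scheme():
    return packaged_scheme()


@pytest.fixture(scope="session")
def sim_scheme():
    """25 sequences in 5 planted clades (within 0.98 / between 0.80)."""
    cfg = SimulationConfig(seed=42, clade_sizes=(5, 5, 5, 5, 5))
    return generate_clade_scheme(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
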
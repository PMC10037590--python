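import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # helpers / oracles

from fraxdef.codesets import default_registry
from fraxdef.definitions import builtin_definitions
from fraxdef.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def hip_defs():
    return builtin_definitions("hip")


@pytest.fixture(scope="session")
def ru_defs():
    return builtin_definitions("radius_ulna")


@pytest.fixture(scope="session")
def sim_small():
    """Mid-size simulated dataset shared by property tests."""
    config = SimulationConfig(seed=20230314, n_patients=5000)
    patients, claims, truths = simulate(config)
    all_claims = [c for v in claims.values() for c in v]
    return config, patients, claims, all_claims, truths


@pytest.fixture(scope="session")
def sim_large():
    """Large dataset for parameter-recovery checks."""
    config = SimulationConfig(seed=53, n_patients=20000)
    patients, claims, truths = simulate(config)
    all_claims = [c for v in claims.values() for c in v]
    return config, patients, claims, all_claims, truths
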
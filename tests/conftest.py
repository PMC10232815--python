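import numpy as np
import pytest

from ectflow.montage import place_electrodes
from ectflow.pipeline import make_fixtures
from ectflow.solver import (
    ConductivityTable,
    assemble_system,
    check_current_conservation,
    compute_efield,
    solve_potential,
)


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=7, size="tiny")


@pytest.fixture(scope="session")
def tiny_params(fixtures):
    return fixtures["phantom_params"]


@pytest.fixture(scope="session")
def tiny_phantom(fixtures):
    return fixtures["phantom"]


@pytest.fixture(scope="session")
def tiny_electrode_kwargs(fixtures):
    return fixtures["electrode"]


def _solve_tiny(fixtures, montage_name):
    vol, montage = place_electrodes(
        fixtures["phantom"], montage_name, 100.0, fixtures["phantom_params"],
        **fixtures["electrode"])
    system = assemble_system(vol, ConductivityTable())
    sol = solve_potential(system, montage, tol=1e-9)
    compute_efield(sol)
    imbalance = check_current_conservation(sol, montage, system)
    return {"volume": vol, "montage": montage, "system": system,
            "solution": sol, "imbalance": imbalance}


@pytest.fixture(scope="session")
def tiny_rul(fixtures):
    return _solve_tiny(fixtures, "RUL")


@pytest.fixture(scope="session")
def tiny_bl(fixtures):
    return _solve_tiny(fixtures, "BL")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
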
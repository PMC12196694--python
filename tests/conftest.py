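import numpy as np
import pytest

from hivcea import (
    CostSchedule,
    ModelConfig,
    ModelInputs,
    StageVector,
    TransitionSchedule,
    UtilitySchedule,
    load_fixtures,
)


@pytest.fixture(scope="session")
def table1():
    """(baseline, utilities, costs) from the packaged published inputs."""
    return load_fixtures("table1")


@pytest.fixture(scope="session")
def table2():
    """Year-specific transition schedule with year-3 carry-forward."""
    return load_fixtures("table2")


@pytest.fixture(scope="session")
def base_inputs(table1, table2):
    baseline, utilities, costs = table1
    return ModelInputs(baseline, table2, costs, utilities, ModelConfig())


@pytest.fixture
def identity_schedule():
    eye = np.eye(4)
    return TransitionSchedule({1: eye, 2: eye, 3: eye})


@pytest.fixture
def uniform_utilities():
    return UtilitySchedule(np.full(4, 0.5))


def random_row_stochastic(rng, n=4):
    m = rng.random((n, n)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)
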
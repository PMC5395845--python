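import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import casemixsim as cm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

MASTER_SEED = 7


@pytest.fixture(scope="session")
def table1_specs():
    return {s.id: s for s in cm.load_table1_specs()}


@pytest.fixture(scope="session")
def table2_specs():
    return {s.id: s for s in cm.load_table2_specs()}


@pytest.fixture(scope="session")
def dev_a1(table1_specs):
    """All 16 approach-1 populations developed at full size under one seed."""
    return cm.develop_all(list(table1_specs.values()), MASTER_SEED)


@pytest.fixture(scope="session")
def dev_a2(table2_specs):
    """All 9 approach-2 populations developed at full size under one seed."""
    return cm.develop_all(list(table2_specs.values()), MASTER_SEED)


@pytest.fixture(scope="session")
def xval_a1(dev_a1):
    return cm.cross_validate(dev_a1.models, dev_a1.cohorts, direction="auto")


@pytest.fixture(scope="session")
def xval_a2(dev_a2):
    return cm.cross_validate(dev_a2.models, dev_a2.cohorts, direction="auto")


@pytest.fixture(scope="session")
def sweep_same(table1_specs):
    """Same-direction-OR correlation sweep over the standard grid."""
    grid = np.round(np.arange(-0.4, 0.401, 0.1), 10)
    return cm.correlation_sweep_a1(table1_specs["A"], grid, or_mode="same", seed=11)


@pytest.fixture(scope="session")
def sweep_opposite(table1_specs):
    grid = np.round(np.arange(-0.4, 0.401, 0.1), 10)
    return cm.correlation_sweep_a1(table1_specs["A"], grid, or_mode="opposite", seed=11)
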
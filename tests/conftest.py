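import numpy as np
import pytest

import strucnet as sn


@pytest.fixture(scope="session")
def atlas():
    return sn.load_default_atlas()


@pytest.fixture
def triangle():
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)


@pytest.fixture
def star4():
    """K_{1,3}: node 0 is the center."""
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


@pytest.fixture
def path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared by inference-facing tests."""
    cfg = sn.SimulationConfig(seed=7, n_controls=12, n_patients=10)
    return sn.simulate_cohort(cfg)
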
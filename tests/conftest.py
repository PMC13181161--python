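import numpy as np
import pytest

from jointwiv import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_joint_data():
    """Small simulated joint dataset shared by fast structural tests."""
    cfg = SimulationConfig(n_subjects=12, seed=3)
    long_data, surv_data, truth = simulate_dataset(cfg)
    return long_data, surv_data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
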
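import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def separable_xy():
    """Two well-separated 1-D point clouds: any sane classifier gets 0 train error."""
    rng = np.random.default_rng(42)
    x0 = rng.normal(0.0, 0.3, size=(20, 1))
    x1 = rng.normal(10.0, 0.3, size=(20, 1))
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], 20)
    return X, y


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default two-group simulation (500 x 40)."""
    from ecfs_dea.simulate import SimulationConfig, generate_simulated_dataset

    return generate_simulated_dataset(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def sim_split(default_sim):
    from ecfs_dea.importance import split_samples

    return split_samples(default_sim.labels, 0.5, 505)
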
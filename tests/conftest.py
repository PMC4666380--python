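import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcrdistort.pipeline import RunConfig, analyze_profile, simulate_experiment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def templates():
    from pcrdistort.templates import default_templates

    return default_templates()


@pytest.fixture(scope="session")
def experiment_cfg():
    """Study-scale synthetic run: 2900 single-molecule inputs, 25 cycles,
    P_amp = 0.9, p_nt = 2.7e-5, s0 = 2.6e-15, mean plateau depth 5000."""
    return RunConfig(seed=1, n_input=2900)


@pytest.fixture(scope="session")
def experiment_profile(experiment_cfg):
    return simulate_experiment(experiment_cfg)


@pytest.fixture(scope="session")
def experiment_estimates(experiment_cfg, experiment_profile):
    return analyze_profile(experiment_profile, experiment_cfg)
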
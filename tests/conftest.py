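import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from floodrisk import build_level_table, enumerate_grid
from floodrisk.experiments import parameter_recovery
from floodrisk.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def default_grid():
    """The 1331-scenario grid under the published loadings."""
    return enumerate_grid()


@pytest.fixture(scope="session")
def default_table(default_grid):
    return build_level_table(default_grid)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def recovery_200():
    """200 replicated fits of n=560 synthetic surveys from the calibrated model.

    Shared between the parameter-recovery checks and the chi-square
    calibration check so the expensive experiment runs once per session.
    """
    return parameter_recovery(n_replicates=200, base_seed=1)
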
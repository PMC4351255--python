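import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from augment_rl.training import run_experiment

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def trained_saccade():
    """One hundred saccade networks trained with the default parameters."""
    result, nets = run_experiment("saccade", n_networks=100, seed=101,
                                  keep_networks=True)
    return result, nets


@pytest.fixture(scope="session")
def trained_category():
    """Six match-to-category networks for the tuning analyses."""
    result, nets = run_experiment("category", n_networks=6, seed=202,
                                  keep_networks=True)
    return result, nets


@pytest.fixture(scope="session")
def trained_vibrotactile():
    """Twelve variable-F1 networks shared by the convergence and
    frequency-coding checks."""
    result, nets = run_experiment("vibrotactile", mode="variable",
                                  n_networks=12, seed=303,
                                  keep_networks=True)
    return result, nets
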
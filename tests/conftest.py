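import numpy as np
import pytest

from pocketgait import RunConfig, default_params, simulate_trial
from pocketgait.pipeline import analyze_trial


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def sim_single():
    """One cohort-typical single-task trial with ground truth (seeded)."""
    params = default_params("single_task", seed=3)
    return simulate_trial(params, condition="single_task", trial_id="fix-single")


@pytest.fixture(scope="session")
def analyzed_single(sim_single, config):
    trial, truth = sim_single
    return analyze_trial(trial, config), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
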
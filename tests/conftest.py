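import warnings

import numpy as np
import pytest

from popigt import (
    FitConfig,
    GeneratorDistributions,
    ORLParams,
    default_task_config,
    parameter_recovery,
    simulate_agent,
)

warnings.filterwarnings("ignore", message=".*boundary.*")


@pytest.fixture(scope="session")
def task_config():
    return default_task_config()


@pytest.fixture(scope="session")
def example_params():
    return ORLParams(A_rew=0.3, A_pun=0.2, beta_f=2.0, beta_b=0.5)


@pytest.fixture(scope="session")
def example_session(task_config, example_params):
    return simulate_agent(example_params, task_config, seed=7)


@pytest.fixture(scope="session")
def recovery_run(task_config):
    """One shared simulate-and-refit study (n=100 subjects, 120 trials),
    reused by the hierarchical-fit and association tests."""
    return parameter_recovery(
        n_subjects=100,
        generator_distributions=GeneratorDistributions(),
        task_config=task_config,
        fit_config=FitConfig(),
        seed=20240,
    )


def random_session(task_config, rng):
    """A session with random parameters and random choices, for oracles."""
    params = ORLParams(
        A_rew=float(rng.uniform(0.01, 0.95)),
        A_pun=float(rng.uniform(0.01, 0.95)),
        beta_f=float(rng.normal(0, 3)),
        beta_b=float(rng.normal(0, 1.5)),
    )
    return params, simulate_agent(params, task_config, seed=int(rng.integers(2**31)))
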
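import numpy as np
import pandas as pd
import pytest

from twostep_ema.hybrid import HybridParams, simulate_agent
from twostep_ema.task import TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def simulate_cohort_trials(param_fn, n_subjects, n_trials, rng, p_common=0.7):
    """Concatenate simulated sessions for a cohort of hybrid agents.

    ``param_fn(i, rng)`` returns the i-th subject's parameters.
    """
    config = TaskConfig(n_trials=n_trials, p_common=p_common)
    frames = [
        simulate_agent(param_fn(i, rng), config, rng, subject=i)
        for i in range(n_subjects)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def mixed_params():
    """A moderately model-based agent with decisive choices."""
    return HybridParams(alpha1=0.6, alpha2=0.6, lam=0.6, beta1=2.0,
                        beta2=2.0, omega=0.6, rep=0.2)
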
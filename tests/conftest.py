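import numpy as np
import pytest

from probjudge import SimParams, generate_experiment1, run_batch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_default_table():
    """One synthetic experiment-1 dataset at default generator settings."""
    return generate_experiment1(39, SimParams(w_mult=0.3, noise_sd=0.05), seed=101)


@pytest.fixture(scope="session")
def mixed_batch():
    """A 2000-run mixed-strategy simulated batch (exact multiplication branch)."""
    return run_batch(
        "uniform", 2000, SimParams(w_mult=0.3, noise_sd=0.05, granularity=None, seed=202)
    )
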
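import numpy as np
import pytest

from mpsprofiler import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_table(default_config):
    """One default synthetic table (2 lines x 12 envs x 3 reps = 72 rows)."""
    return generate_dataset(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
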
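import numpy as np
import pandas as pd
import pytest

from chemoresponse.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale planted cohort used across module tests."""
    return SimConfig(n_samples=180, n_genes=300, n_cpg=150,
                     planted_segment=("1", 50, 25), n_planted_cpg=30,
                     n_decoy_confounded=8, n_batches=6, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def surv(times, events):
    """Build a survival outcome frame from parallel lists."""
    idx = [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=idx)


@pytest.fixture()
def surv_factory():
    return surv
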
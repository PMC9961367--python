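import numpy as np
import pytest

import popgraph_stager as pg


@pytest.fixture(scope="session")
def small_config():
    """Compact three-class cohort used across module tests."""
    return pg.CohortConfig(
        class_counts={"CN": 30, "MCI": 30, "AD": 30},
        feature_dim=16,
        class_separation=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return pg.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_config):
    return pg.generate_features(small_cohort, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
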
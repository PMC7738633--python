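import logging

import numpy as np
import pytest

from pdacgrowth import GeneratorConfig, generate_cohort

logging.getLogger("pdacgrowth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 55-patient synthetic cohort (26 low / 29 high delta)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_truth(default_cohort):
    return default_cohort.metadata["truth"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
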
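import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from pengkrill import pipeline, synthetic

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_scenario():
    """A small season used by unit tests that need a full bundle quickly."""
    return dataclasses.replace(synthetic.GOOD_SEASON, n_birds=2,
                               n_trips_per_bird=3, seed=77)


@pytest.fixture(scope="session")
def mini_bundle(mini_scenario):
    return synthetic.simulate_season(mini_scenario)


@pytest.fixture(scope="session")
def default_pipeline():
    """The full two-season pipeline under pure default configuration."""
    return pipeline.run_pipeline(pipeline.PipelineConfig())
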
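import numpy as np
import pytest

from phsupply import entropy_index, synthetic_data
from phsupply.panel_io import RegionPartition


@pytest.fixture(scope="session")
def default_config():
    return synthetic_data.GeneratorConfig(seed=12345)


@pytest.fixture(scope="session")
def geography(default_config):
    return synthetic_data.make_geography(default_config)


@pytest.fixture(scope="session")
def indicator_panel(default_config, geography):
    panel, truth = synthetic_data.make_indicator_panel(default_config, geography)
    return panel, truth


@pytest.fixture(scope="session")
def score_panel(indicator_panel):
    panel, _ = indicator_panel
    std = entropy_index.standardize(panel)
    weights = entropy_index.entropy_weights(std)
    return entropy_index.compose_score(std, weights)


@pytest.fixture(scope="session")
def partition(default_config):
    return synthetic_data.default_partition(default_config)


@pytest.fixture(scope="session")
def covariate_panel(default_config):
    cov, truth = synthetic_data.make_covariate_panel(default_config)
    return cov, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture()
def two_region_partition():
    return RegionPartition.from_mapping(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ("A", "B")
    )
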
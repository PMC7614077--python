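import numpy as np
import pytest

from ilptrack import (
    CandidateParams,
    SimConfig,
    extract_graph,
    render_predictions,
    simulate_lineages,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small zero-noise simulated dataset with divisions and exits."""
    config = SimConfig(shape=(16, 16, 48, 48), n_initial=8, seed=7)
    forest = simulate_lineages(config)
    indicator, movement, foreground = render_predictions(forest, config)
    return config, forest, indicator, movement, foreground


@pytest.fixture(scope="session")
def small_graph(small_sim):
    config, forest, indicator, movement, _fg = small_sim
    return extract_graph(indicator, movement, CandidateParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
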
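import numpy as np
import pytest

from ecg_graphnet import (GraphConfig, MorphologyConfig, build_graph,
                          fit_segment_autoencoders, generate_dataset)


@pytest.fixture(scope="session")
def morph():
    return MorphologyConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """12 patients × 3 records at the study class mixture (~400 beats)."""
    return generate_dataset(12, 3, seed=42)


@pytest.fixture(scope="session")
def trained_aes(small_dataset):
    return fit_segment_autoencoders(small_dataset, seed=7)


@pytest.fixture(scope="session")
def small_graphs(small_dataset, trained_aes):
    return [build_graph(r, trained_aes, GraphConfig()) for r in small_dataset]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
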
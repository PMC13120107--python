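import numpy as np
import pytest

from radarfall.bcnn import NetworkSpec, TrainConfig
from radarfall.pipeline import preprocess_corpus
from radarfall.radarsim import SimConfig, generate_dataset
from radarfall.training import train_detailed


@pytest.fixture(scope="session")
def seed0_corpus():
    """Default synthetic corpus: 40 frames per activity class, seed 0."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def seed0_dataset(seed0_corpus):
    """Binary spectrograms of the seed-0 corpus (fixed-point pipeline)."""
    return preprocess_corpus(seed0_corpus)


@pytest.fixture(scope="session")
def net8_result(seed0_dataset):
    """The selected 3-conv architecture trained on the seed-0 corpus."""
    spec = NetworkSpec((32, 32, 32), (32, 2))
    cfg = TrainConfig(epochs=60, seed=0)
    return train_detailed(seed0_dataset, spec, cfg)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Two frames per class, for pipeline-level checks."""
    return generate_dataset(SimConfig(seed=3, n_per_class={c: 2 for c in "abcdefghijkl"}))
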
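import numpy as np
import pytest

from sndm import (ModelConfig, SceneParams, TrainConfig, build_model,
                  generate_scene_set, train)
from sndm.synth import TruncatedExponentialCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_params():
    """Small scenes with modest counts for fast end-to-end tests."""
    return SceneParams(
        image_size=48, seed=9,
        count_distribution=TruncatedExponentialCounts(max_count=25, mean=8))


@pytest.fixture(scope="session")
def tiny_splits(tiny_params):
    ds = generate_scene_set(18, tiny_params)
    return {"train": ds.subset(range(12)), "val": ds.subset(range(12, 15)),
            "test": ds.subset(range(15, 18))}


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(mode="sndm", input_size=48, n_stages=3,
                       base_channels=8, dropout_rate=0.1, seed=3)


@pytest.fixture(scope="session")
def tiny_trained(tiny_splits, tiny_model_config):
    """One briefly trained sndm miniature, shared across tests."""
    model = build_model(tiny_model_config)
    result = train(model, tiny_splits["train"], tiny_splits["val"],
                   TrainConfig(max_epochs=3, patience=3, learning_rate=2e-3,
                               seed=5))
    return model, result
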
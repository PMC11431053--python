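import numpy as np
import pytest

from octex import synthetic as syn
from octex.network import ModelConfig
from octex.training import TrainConfig, train


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic geometry for fast unit tests: 3 windows/frame."""
    return syn.SyntheticConfig(
        frame_count=6, frame_height=64, frame_width=192,
        window_size=64, stride=32,
    )


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(backbone_profile="test", n_textons=4, texton_dim=16)


@pytest.fixture(scope="session")
def trained_model():
    """A test-profile classifier trained briefly on a small synthetic cohort.

    Shared (session-scoped) by the interpretability and voting tests; good
    enough to separate the motif classes, not tuned to any particular test.
    """
    cfg = syn.SyntheticConfig()
    mix = {"MI": 0.15, "CY": 0.15, "EP": 0.14, "HSIL": 0.28, "CC": 0.28}
    cohort = syn.generate_cohort(14, mix, 1, cfg, seed=7)
    ds = syn.generate_patch_dataset(cohort)
    mc = ModelConfig(backbone_profile="test", n_textons=8, texton_dim=32)
    tc = TrainConfig(epochs=8, seed=0, input_size=128)
    result = train(ds.patches, ds.labels, mc, tc)
    return result
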
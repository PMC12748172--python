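import numpy as np
import pytest

from vesseltext.model_pipeline import ModelConfig, TrainConfig, load_dataset
from vesseltext.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """32x32 profile used by training tests (fast on one CPU)."""
    return ModelConfig(input_size=(32, 32), depth=3, base_channels=4,
                       vit_dim=16, heads=2)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """Small on-disk OCTA-mode dataset shared across training tests."""
    out = tmp_path_factory.mktemp("synth") / "octa32"
    cfg = SynthConfig.octa(size=(32, 32), seed=11)
    generate_dataset(cfg, n_train=4, n_test=2, out_dir=out)
    return out


@pytest.fixture(scope="session")
def tiny_train_set(tiny_dataset_dir, tiny_model_cfg):
    return load_dataset(tiny_dataset_dir, "train", tiny_model_cfg,
                        apply_preprocessing=False)


@pytest.fixture(scope="session")
def tiny_test_set(tiny_dataset_dir, tiny_model_cfg):
    return load_dataset(tiny_dataset_dir, "test", tiny_model_cfg,
                        apply_preprocessing=False)


@pytest.fixture
def tiny_train_cfg():
    return TrainConfig(epochs=1, batch_size=2, seed=3)
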
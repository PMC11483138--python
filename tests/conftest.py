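import numpy as np
import pytest

from screcon.data_io import normalize_pair
from screcon.model import ModelConfig
from screcon.synthetic import SimConfig, generate_paired
from screcon.training import TrainConfig


@pytest.fixture(scope="session")
def tiny_pair():
    """A small normalized paired dataset shared across read-only tests."""
    cfg = SimConfig(n_sc=40, n_st=30, n_genes=20, n_pattern_genes=6, seed=7)
    ds, truth = generate_paired(cfg)
    return normalize_pair(ds), truth


@pytest.fixture()
def tiny_model_config():
    return ModelConfig(scales=(8, 16), decoder_hidden=16, dtype="float64")


@pytest.fixture()
def tiny_train_config():
    return TrainConfig(epochs=30, learning_rate=1e-3, seed=0)
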
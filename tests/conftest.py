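import dataclasses

import numpy as np
import pytest

from trapnet.synthetic_data import DomainParams, DomainShiftSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_spec():
    """A tiny 3-class, 32x32 benchmark for fast pipeline tests."""
    return DomainShiftSpec(
        n_classes=3,
        img_size=32,
        n_per_class_per_domain=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_dataset_dir(tmp_path_factory, mini_spec):
    """Rendered PNGs + manifest for the tiny benchmark."""
    from trapnet.synthetic_data import generate_dataset

    out = tmp_path_factory.mktemp("mini_benchmark")
    generate_dataset(mini_spec, out)
    return out


def mini_train_config(**overrides):
    """Small config that trains in seconds on the tiny benchmark."""
    from trapnet.trainer import TrainConfig

    base = dict(
        n_classes=3,
        img_size=32,
        batch_size=8,
        iterations=12,
        backbone_channels=(4, 8, 16),
        disc_hidden=(16, 16),
        d_model=32,
        n_heads=2,
        d_ff=32,
        log_every=1,
        seed=0,
    )
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture
def mini_config():
    return mini_train_config()
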
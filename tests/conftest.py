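import pytest
from hypothesis import settings

from cnvimpact import CnvType
from cnvimpact.dataset import split_train_val_test
from cnvimpact.model import train_classifier
from cnvimpact.synthetic import (
    ToyGenomeSpec,
    build_toy_genome,
    sample_feature_dataset,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def loss_splits():
    """Moment-matched loss dataset (2000 + 2000), split 70/15/15."""
    ds = sample_feature_dataset(CnvType.LOSS, 2000, 2000, seed=11)
    return split_train_val_test(ds.X, ds.y, CnvType.LOSS, seed=11)


@pytest.fixture(scope="session")
def loss_model(loss_splits):
    train, val, _ = loss_splits
    return train_classifier(train, val, seed=11)


@pytest.fixture(scope="session")
def gain_splits():
    ds = sample_feature_dataset(CnvType.GAIN, 800, 800, seed=3)
    return split_train_val_test(ds.X, ds.y, CnvType.GAIN, seed=3)


@pytest.fixture(scope="session")
def gain_model(gain_splits):
    train, val, _ = gain_splits
    return train_classifier(train, val, seed=3)


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome(ToyGenomeSpec(seed=5))
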
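import numpy as np
import pytest

import emgforce as ef


@pytest.fixture(scope="session")
def default_cfg():
    return ef.SynthConfig(seed=42)


@pytest.fixture(scope="session")
def dataset5(default_cfg):
    """The default 5-trial synthetic dataset (master seed 42)."""
    return ef.make_dataset(5, default_cfg)


@pytest.fixture(scope="session")
def features5(dataset5):
    return [ef.feature_matrix(ef.preprocess_chain(rec), spec=ef.WindowSpec())
            for rec in dataset5]


@pytest.fixture(scope="session")
def trained5(features5):
    """Model + report trained on the default dataset (seed 42)."""
    return ef.fit_trials(features5, ef.TrainConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
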
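import datetime as dt

import numpy as np
import pytest

from woundrisk.engines import load_default_config
from woundrisk.fusion import DecisionFactorModel
from woundrisk.synthetic import SyntheticWoundSpec


@pytest.fixture(scope="session")
def technical_config():
    return load_default_config("technical")


@pytest.fixture(scope="session")
def expert_config():
    return load_default_config("expert")


@pytest.fixture(scope="session")
def model():
    return DecisionFactorModel()


@pytest.fixture
def clean_spec():
    """Noise-free synthetic wound image spec."""
    return SyntheticWoundSpec(noise_sigma=0.0, seed=0)


@pytest.fixture
def noisy_spec():
    return SyntheticWoundSpec(noise_sigma=0.02, seed=1)


@pytest.fixture(scope="session")
def worked_case_dates():
    return dt.date(2019, 6, 25), dt.date(2019, 7, 25)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190625)
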
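import numpy as np
import pytest

from fir.cims_model import EncodingDistribution, ModelConfig, RepresentationalSpace
from fir.dataset_io import main_stimuli


@pytest.fixture(scope="session")
def model_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def stimuli():
    return main_stimuli()


@pytest.fixture(scope="session")
def s1_space(model_config, stimuli) -> RepresentationalSpace:
    return model_config.space_for(stimuli["S1"])


@pytest.fixture(scope="session")
def s1_encoders(model_config, s1_space):
    return model_config.encoders_for(s1_space)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
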
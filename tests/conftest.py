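import numpy as np
import pytest

from loomdef import (ArenaConfig, BehaviorGenParams, StimulusSpec,
                     synth_crescendo_train, stimulus_windows)


@pytest.fixture(scope="session")
def default_spec():
    return StimulusSpec()


@pytest.fixture(scope="session")
def default_train(default_spec):
    return synth_crescendo_train(default_spec, seed=0)


@pytest.fixture(scope="session")
def default_windows(default_train):
    return stimulus_windows(default_train)


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def behavior_params():
    return BehaviorGenParams(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
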
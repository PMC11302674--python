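import numpy as np
import pytest

from ethoseg.features import FeatureSequence, LabelSequence
from ethoseg.generative import sample_rslds, well_separated_preset


@pytest.fixture(scope="session")
def preset_params():
    return well_separated_preset()


@pytest.fixture(scope="session")
def small_trajectory(preset_params):
    return sample_rslds(preset_params, 600, seed=42)


@pytest.fixture
def small_session(small_trajectory):
    fs = FeatureSequence(small_trajectory.x)
    ls = LabelSequence(small_trajectory.y, ["state0", "state1"])
    return fs, ls
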
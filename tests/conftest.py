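import numpy as np
import pytest

from predlearn.designs import (build_exp1_design, build_exp2_design,
                               build_lepelley_design)
from predlearn.gaze_pipeline import RoiLayout
from predlearn.synthetic_data import default_profile, generate_participant


@pytest.fixture(scope="session")
def exp1_design():
    return build_exp1_design(seed=1)


@pytest.fixture(scope="session")
def exp2_serial_stimuli():
    return build_exp2_design("Serial-Stimuli", seed=1)


@pytest.fixture(scope="session")
def lepelley20():
    return build_lepelley_design(n_blocks=20, seed=0)


@pytest.fixture(scope="session")
def layout():
    return RoiLayout.default()


@pytest.fixture(scope="session")
def serial_stimuli_participant(exp2_serial_stimuli):
    profile = default_profile("Serial-Stimuli", dwell_bias_effect=0.06)
    return generate_participant(exp2_serial_stimuli, profile, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
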
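import numpy as np
import pytest

from fogait.data_io import GpdParams
from fogait.gait_segmentation import segment_recording
from fogait.synthetic_gait import FogScenario, GaitProfile, simulate_recording


@pytest.fixture(scope="session")
def params():
    return GpdParams()


@pytest.fixture(scope="session")
def clean_gait():
    """10 normal strides, seed 1, with ground truth and rater annotations."""
    return simulate_recording([FogScenario(mode="normal", n_steps=10)], seed=1)


@pytest.fixture(scope="session")
def segmented(clean_gait, params):
    series, _, _ = clean_gait
    return segment_recording(series, params, return_kinematics=True)


@pytest.fixture(scope="session")
def festination_burst():
    """5 fast steps without inter-step rest, seed 2."""
    return simulate_recording([FogScenario(mode="festination", n_steps=5)], seed=2)


@pytest.fixture(scope="session")
def noiseless_profile():
    return GaitProfile(noise_sd_acc=0.0, noise_sd_gyro=0.0, contact_spike=0.0)
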
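import numpy as np
import pytest

from msiperf import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study (2 distances, 1 participant each,
    4 blocks, 32x32 px) shared across pipeline/IO tests."""
    design = phantom.StudyDesign(
        measurements_per_participant=4,
        participants_per_distance=1,
        distances_mm=(35.0, 45.0),
    )
    return phantom.run_synthetic_study(design=design, seed=7, shape=(32, 32), snr_frames=12)


@pytest.fixture(scope="session")
def default_study_scaled():
    """The full default study design at reduced image size."""
    return phantom.run_synthetic_study(seed=3, shape=(32, 32), snr_frames=64)
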
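import numpy as np
import pytest

from strokeqeeg import (
    SeverityProfile,
    bandpass_filter,
    generate_eeg,
    select_clean_segment,
)


@pytest.fixture(scope="session")
def moderate_recording():
    """Artifact-free 130 s recording at mid severity, already bandpassed."""
    profile = SeverityProfile.from_severity(0.5)
    rec = generate_eeg(profile, duration_s=130.0, fs=128.0, n_channels=19, seed=42)
    return bandpass_filter(rec)


@pytest.fixture(scope="session")
def clean_segment(moderate_recording):
    return select_clean_segment(moderate_recording, target_s=120.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
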
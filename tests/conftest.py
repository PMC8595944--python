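import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Two minutes of artifact-free 8-channel synthetic EEG."""
    from somnospec import EEGSynthesisSpec, synthesize_eeg

    return synthesize_eeg(EEGSynthesisSpec(duration=120.0, seed=42))
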
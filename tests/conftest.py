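import numpy as np
import pytest

from apnet.spectral_connectivity import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def noise_recording(rng):
    """A small 4-channel white-noise recording (32 s at 128 Hz)."""
    return EEGRecording(
        subject_id="s1",
        condition="EO",
        fs=128.0,
        channel_labels=("a", "b", "c", "d"),
        data=rng.standard_normal((4, 32 * 128)),
    )
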
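import numpy as np
import pytest

from dryeeg.preprocess import DEFAULT_ELECTRODES, RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eight_channel_recording(rng):
    """60 s of random 8-electrode signal at 500 Hz (no structure needed)."""
    sig = rng.standard_normal((8, 30000)) * 20.0
    return RawRecording(
        signal=sig,
        rate=500.0,
        channel_names=list(DEFAULT_ELECTRODES),
        subject_id="subA",
        session_id="ses01",
    )
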
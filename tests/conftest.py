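import numpy as np
import pytest

from vnspredict.recording import CHANNELS_1020, EegRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=250.0, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = list(CHANNELS_1020[: data.shape[0]])
    return EegRecording(data=data, sampling_rate=fs, channel_labels=labels)


@pytest.fixture
def sine_recording():
    """Two-channel 10 Hz / 6 Hz sinusoids, 8 s at 250 Hz."""
    fs = 250.0
    t = np.arange(int(8 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 6 * t)])
    return make_recording(data, fs=fs, labels=["C3", "C4"])
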
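import numpy as np
import pytest

from amdyn import Epoch

FS = 256.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoch(signal, fs=FS, channels=None, task="ROT", trial=0):
    signal = np.atleast_2d(signal)
    if channels is None:
        channels = [f"ch{i}" for i in range(signal.shape[0])]
    return Epoch(signal=signal, fs=fs, channel_labels=list(channels),
                 task=task, participant="S1", session="1", trial=trial)


@pytest.fixture
def am_epoch(fs):
    """Single-channel 16 s epoch: 10 Hz carrier with 2 Hz sinusoidal AM,
    depth 0.5."""
    t = np.arange(int(16 * fs)) / fs
    x = (1 + 0.5 * np.sin(2 * np.pi * 2 * t)) * np.sin(2 * np.pi * 10 * t)
    return make_epoch(x, fs, channels=["C3"])
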
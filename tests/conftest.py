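import numpy as np
import pytest

from eegcube import RawRecording, load_montage


@pytest.fixture(scope="session")
def montage():
    return load_montage("seed62")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(montage, rng):
    """A 2-s, 62-channel recording of white noise at 200 Hz."""
    data = rng.normal(size=(montage.n_channels, 400))
    return RawRecording(data, fs=200.0, label=1, subject_id=0, session_id=0,
                        trial_id=0, channel_names=montage.channel_names)


def separable_toy(n=200, d=2, separation=10.0, seed=0):
    """Two Gaussian clouds separated by ``separation`` standard deviations."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n // 2, d))
    x1 = rng.normal(0.0, 1.0, size=(n - n // 2, d)) + separation
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], [n // 2, n - n // 2])
    perm = rng.permutation(n)
    return x[perm], y[perm]
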
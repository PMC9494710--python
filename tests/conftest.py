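import numpy as np
import pytest

from semglite import GestureProtocol, RawRecording, generate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_protocol():
    """A scaled-down gesture protocol for fast pipeline tests."""
    return GestureProtocol(
        n_classes=4,
        repetitions=2,
        trial_duration_s=1.0,
        rest_duration_s=0.2,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_trials(tiny_protocol):
    return generate_trials(tiny_protocol)


@pytest.fixture
def tone_recording():
    """Factory for single-frequency six-channel test recordings."""

    def make(freq_hz: float, fs: float = 2000.0, duration_s: float = 2.0, n_channels: int = 6):
        t = np.arange(int(duration_s * fs)) / fs
        x = np.sin(2 * np.pi * freq_hz * t)
        return RawRecording(np.tile(x[:, None], (1, n_channels)), fs=fs)

    return make


def steady_rms(x: np.ndarray, fs: float) -> float:
    """RMS over the middle of a signal, clear of filter edge transients."""
    n = len(x)
    lo, hi = int(0.25 * n), int(0.75 * n)
    return float(np.sqrt(np.mean(np.square(x[lo:hi]))))
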
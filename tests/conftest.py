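import numpy as np
import pytest

from emokan.bands import CHANNELS, EEGWindow


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_window(signals: dict, fs: float = 128.0, seconds: float = 1.0) -> EEGWindow:
    """Build a window from per-channel callables of the time vector."""
    t = np.arange(int(fs * seconds)) / fs
    samples = np.column_stack([
        signals.get(ch, lambda tt: np.zeros_like(tt))(t) for ch in CHANNELS
    ])
    return EEGWindow(samples, fs)


@pytest.fixture
def sine_window():
    def factory(freq: float, amplitude: float = 1.0, fs: float = 128.0, phase: float = 0.0):
        return make_window(
            {ch: (lambda tt, a=amplitude: a * np.sin(2 * np.pi * freq * tt + phase))
             for ch in CHANNELS}, fs=fs)
    return factory


@pytest.fixture
def noise_window(rng):
    def factory(scale: float = 1.0, fs: float = 128.0, seed: int | None = None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return EEGWindow(scale * r.standard_normal((int(fs), len(CHANNELS))), fs)
    return factory
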
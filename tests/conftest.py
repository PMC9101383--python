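"""Shared fixtures: tiny deterministic spectrograms and a cached study."""

import numpy as np
import pytest

from soundscapemap.audio import Spectrogram, SpectrogramParams


def make_block(A, rate=48000.0, window_len=1024, f0=0.0):
    """Wrap a plain matrix as a Spectrogram block for index unit tests.

    Rows are frequency bins spaced at the params' FR starting at ``f0``.
    """
    A = np.asarray(A, dtype=float)
    params = SpectrogramParams(window_len=window_len)
    fr = rate / window_len
    freqs = f0 + fr * np.arange(A.shape[0])
    times = (window_len / rate) * np.arange(A.shape[1])
    return Spectrogram(A=A, freqs=freqs, times=times, params=params, rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """One rendered 16-site study at 20 s/site, shared across tests."""
    from soundscapemap.synth import StudyConfig, generate_study

    return generate_study(StudyConfig(seed=7, duration=20.0))
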
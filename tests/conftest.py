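import numpy as np
import pytest

import tfs1kit as tk
from tfs1kit import spikes as sp


@pytest.fixture(scope="session")
def tone_1khz():
    """0.4 s pure tone at 1 kHz, 48 kHz sample rate."""
    fs = 48000.0
    t = np.arange(int(0.4 * fs)) / fs
    return tk.StimulusWaveform(0.1 * np.cos(2 * np.pi * 1000.0 * t), fs)


@pytest.fixture(scope="session")
def tfs1_400_1600():
    """Harmonic/inharmonic pair for the 400/1600 Hz condition (8% shift)."""
    h = tk.StimulusCondition(f0=400, fc=1600, filter_order=3, seed=1)
    i = h.pair(8.0)
    return tk.synthesize_complex(h), tk.synthesize_complex(i)


@pytest.fixture
def uniform_trains():
    """Unlocked (uniform-random) spike trains: the Rayleigh null."""
    def make(n_reps=10, mean_count=40, seed=0):
        rng = np.random.default_rng(seed)
        times = [np.sort(rng.uniform(0.0125, 0.3875, rng.poisson(mean_count)))
                 for _ in range(n_reps)]
        return sp.SpikeTrainSet(times)
    return make
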
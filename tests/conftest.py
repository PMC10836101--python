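import numpy as np
import pandas as pd
import pytest

import fxseeg as fx

#: fixed base seed for every randomized test in the suite
SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def four_channel_regions():
    return fx.make_region_map(["E1", "E2"], ["E3", "E4"], ["E1", "E2", "E3", "E4"])


def sine_recording(freq=10.0, amplitude=1.0, sfreq=500.0, n_epochs=3, n_channels=4,
                   noise=0.0, seed=SEED, task="rest"):
    """Minimal resting recording: one sinusoid (+ optional white noise)."""
    rng = np.random.default_rng(seed)
    n = int(2 * sfreq)
    t = np.arange(n_epochs * n) / sfreq
    x = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_channels, 1))
    if noise:
        data = data + rng.normal(0, noise, data.shape)
    data = data.reshape(n_channels, n_epochs, n)
    return fx.EpochedRecording(data, sfreq, [f"E{i+1}" for i in range(n_channels)], task=task)


def phase_cube(phases, n_freqs=5, n_times=8, amplitudes=None):
    """Synthetic TF cube whose trial k has constant phase ``phases[k]``."""
    phases = np.asarray(phases, dtype=float)
    amp = np.ones_like(phases) if amplitudes is None else np.asarray(amplitudes, float)
    coeffs = (amp[:, None, None] * np.exp(1j * phases[:, None, None])) * np.ones((1, n_freqs, n_times))
    freqs = np.arange(4.0, 4.0 + n_freqs)
    times = np.linspace(0.1, 0.8, n_times)
    cycles = fx.chirp.n_cycles_for(freqs, 2.0, 100.0)
    valid = np.ones((n_freqs, n_times), dtype=bool)
    return fx.TimeFrequencyCube(coeffs, freqs, times, cycles, valid, 100.0)


@pytest.fixture(scope="session")
def two_gaussian_table():
    """Univariate N(0,1) vs N(2,1) table, 500 per class."""
    rng = np.random.default_rng(SEED)
    n = 500
    x = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
    return pd.DataFrame({
        "participant_id": [f"S{i}" for i in range(2 * n)],
        "group": ["FXS"] * n + ["CON"] * n,
        "sex": ["M"] * (2 * n),
        "mosaic": [False] * (2 * n),
        "x": x,
    })
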
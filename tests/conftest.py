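import numpy as np
import pytest

from gradspike import (
    GroundTruth, SimConfig, WaveformSet, make_templates, simulate_waveform_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_waveform_set(rng):
    """20 random spikes, 64 samples, with labels and overlap flags."""
    waves = rng.standard_normal((20, 64))
    times = np.sort(rng.uniform(0, 10, 20))
    labels = rng.integers(0, 3, 20)
    overlap = rng.random(20) < 0.2
    return WaveformSet(waves, times, 24000.0, labels=labels, overlap_flags=overlap)


def separated_sim(n_units=3, seed=0, duration=40.0, noise=0.1):
    """Labeled snippets from morphologically well-separated units.

    The bank enforces pairwise max-lag cross-correlation < 0.9, the
    quantitative reading of 'well-separated' used throughout the tests.
    """
    bank = make_templates(n_units, 64, seed=seed + 100, max_xcorr=0.9)
    cfg = SimConfig(n_units=n_units, duration=duration,
                    rates=np.full(n_units, 5.0), noise_level=noise, seed=seed)
    return simulate_waveform_set(cfg, bank)


@pytest.fixture
def three_unit_set():
    return separated_sim(3, seed=0)
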
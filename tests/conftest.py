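import numpy as np
import pytest

from echolabel import StftParams, Waveform
from echolabel.fixtures import SyntheticEvent, make_signal

SR = 24_000


@pytest.fixture(scope="session")
def default_params() -> StftParams:
    return StftParams()


@pytest.fixture(scope="session")
def tone_clip() -> Waveform:
    """15 s clip with a single tapered 2 kHz tone, no background noise."""
    return make_signal(
        [SyntheticEvent("tone", 0.5, 14.5, 2.0, 2.0, amplitude=0.5)],
        duration=15.0,
        sample_rate=SR,
        noise_floor=0.0,
        seed=7,
    )


def multitone(seed: int, n_samples: int = 48_000, sample_rate: int = SR, n_tones: int = 8) -> Waveform:
    """Random band-limited signal: tones on exact STFT bin frequencies below 0.8*Nyquist.

    Exact-bin frequencies leave the (discarded) Nyquist bin empty, so these
    signals are fully representable by the half-spectrum STFT.
    """
    rng = np.random.default_rng(seed)
    n = StftParams().window_length
    ks = rng.integers(1, int(0.8 * n / 2), size=n_tones)
    amps = rng.uniform(0.02, 0.1, size=n_tones)
    phases = rng.uniform(0, 2 * np.pi, size=n_tones)
    t = np.arange(n_samples) / sample_rate
    x = np.zeros(n_samples)
    for k, a, p in zip(ks, amps, phases):
        x += a * np.sin(2 * np.pi * (k * sample_rate / n) * t + p)
    return Waveform(samples=x, sample_rate=sample_rate)
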
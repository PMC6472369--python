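import numpy as np
import pytest

from thetalink import TimeSeriesRecording
from thetalink.simulate import BandSource, SharedSourceSpec


@pytest.fixture
def theta_spec() -> SharedSourceSpec:
    """One shared theta source over independent broadband noise."""
    return SharedSourceSpec(
        bands=(BandSource(8.0, 4.0, 4.0, 1.0, 0.7),),
        noise_power_a=1.0,
        noise_power_b=1.0,
    )


@pytest.fixture
def balanced_spec() -> SharedSourceSpec:
    """Equal source and noise PSDs at unit gains: squared coherence 1/4."""
    return SharedSourceSpec(
        bands=(BandSource(8.0, 4.0, 1.0, 1.0, 1.0),),
        noise_power_a=1.0,
        noise_power_b=1.0,
    )


@pytest.fixture
def white_recording() -> TimeSeriesRecording:
    rng = np.random.default_rng(11)
    return TimeSeriesRecording(
        rng.standard_normal((60000, 2)), 1000.0, ("dHipp", "PFC")
    )


def sinusoid_recording(
    f_hz: float = 8.0, fs: float = 1000.0, duration_s: float = 10.0, amp: float = 1.0
) -> TimeSeriesRecording:
    t = np.arange(int(duration_s * fs)) / fs
    return TimeSeriesRecording(amp * np.sin(2 * np.pi * f_hz * t)[:, None], fs, ("x",))
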
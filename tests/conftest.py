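import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mycospike.recording import Recording
from mycospike.simulate import SyntheticConfig, generate_recording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_recording(potentials, dt=1.0, spacing_cm=2.0, labels=None, times=None):
    """Build a small Recording from a (n_samples, n_channels) array."""
    pots = np.asarray(potentials, dtype=float)
    n, c = pots.shape
    if times is None:
        times = np.arange(n) * dt
    if labels is None:
        labels = tuple(f"ch{i + 1}" for i in range(c))
    return Recording(channel_labels=labels, times=times, potentials=pots,
                     sampling_interval=dt, spacing_cm=spacing_cm)


def plateau_trace(n_samples, start, length, height):
    """Two-channel trace: channel 0 is zero apart from a rectangular plateau
    (baseline stays at 0, the plateau supplies the variance); channel 1 is a
    square wave so the recording has the required second channel."""
    pots = np.zeros((n_samples, 2))
    pots[:, 1] = 0.1 * np.where(np.arange(n_samples) % 2 == 0, 1.0, -1.0)
    pots[start:start + length, 0] = height
    return make_recording(pots)


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-configuration synthetic recording with ground truth."""
    return generate_recording(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def small_synthetic():
    """A shorter 4-channel recording for fast unit-level pipeline tests."""
    cfg = SyntheticConfig(n_channels=4, duration_s=5e4, seed=7)
    return generate_recording(cfg, seed=7)
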
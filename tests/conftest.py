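import numpy as np
import pytest

from pbciscreen.recording import EEG, EOG, Recording
from pbciscreen.synthetic import CohortConfig


def make_recording(
    duration: float = 60.0,
    rate: float = 256.0,
    channels=("Fp1", "Fp2"),
    roles=None,
    fill=None,
    rng=None,
):
    """Small helper: a recording filled with noise (default) or a callable of t."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if fill is None:
        rng = rng or np.random.default_rng(0)
        data = rng.standard_normal((len(channels), n))
    else:
        data = np.vstack([np.asarray(fill(t, i), dtype=float) for i in range(len(channels))])
    if roles is None:
        roles = [EOG if c.upper().startswith("EOG") else EEG for c in channels]
    return Recording(data, rate, list(channels), list(roles))


@pytest.fixture
def sine_recording():
    """Two-channel 10 Hz sinusoid, amplitude 2 on Fp1 and 1 on Fp2, 60 s at 256 Hz."""
    return make_recording(
        fill=lambda t, i: (2.0 if i == 0 else 1.0) * np.sin(2 * np.pi * 10.0 * t)
    )


@pytest.fixture
def small_cohort_config():
    """Fast cohort: 5 participants, 20-s sessions, 256 Hz native."""
    return CohortConfig(
        n_participants=5,
        native_rate=256.0,
        resting_duration=20.0,
        task_durations=(("valence", 20.0), ("relaxation", 20.0), ("attention", 20.0)),
        seed=11,
    )
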
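import numpy as np
import pytest

import expectdecode as ed


@pytest.fixture(scope="session")
def default_schedule():
    """Full 10-block, 72-trials-per-block session at 75/75 validity."""
    return ed.generate_schedule(seed=1)


@pytest.fixture(scope="session")
def small_schedule():
    """Compact 128-trial session (multiple of 16) for closed-loop tests."""
    return ed.generate_schedule(2, 64, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def single_timepoint_dataset(schedule, n_sensors=16, snr=1.0, seed=0):
    """One-sample epoch for fast per-timepoint analyses."""
    # signal window straddles t=0 so the raised-cosine profile is 1 there
    tuning = ed.TuningConfig(n_sensors=n_sensors, snr=snr,
                             signal_window_ms=(-2.0, 2.0))
    return ed.simulate_eeg(schedule, tuning, seed=seed,
                           epoch_window_ms=(0.0, 1000.0 / 256.0))
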
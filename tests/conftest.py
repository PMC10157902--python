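import numpy as np
import pandas as pd
import pytest

from bcistim import CHANNELS_1020, EventTable, RawRecording
from bcistim.synthetic import SyntheticConfig, generate_subject

FS = 300.0


@pytest.fixture(scope="session")
def small_config():
    """A fast subject: 10 trials/block, both sessions."""
    return SyntheticConfig(seed=7, n_trials_per_block=10)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return generate_subject(small_config)


@pytest.fixture(scope="session")
def pre_only_subject():
    cfg = SyntheticConfig(seed=3, n_trials_per_block=10, sessions=("pre",))
    return generate_subject(cfg)


def sinusoid_trials(freq, n_trials, seed=0, amp=10.0, fs=FS):
    """Continuous recording of pure-sinusoid trials (7 s each, onset at 1.5 s)
    with per-trial random phase, plus matching events and truth phase tracks."""
    rng = np.random.default_rng(seed)
    trial_len = round(7 * fs)
    onset_in = round(1.5 * fs)
    x = np.zeros(trial_len * n_trials)
    rows, tracks = [], {}
    for i in range(n_trials):
        phi0 = rng.uniform(0, 2 * np.pi)
        t = (np.arange(trial_len) - onset_in) / fs
        x[i * trial_len : (i + 1) * trial_len] = amp * np.cos(2 * np.pi * freq * t + phi0)
        rows.append(
            dict(onset_sample=i * trial_len + onset_in, **{"class": "left"},
                 block=1, phase="offline", session="pre")
        )
        ts = np.arange(round(4 * fs)) / fs
        tracks[i] = np.mod(2 * np.pi * freq * ts + phi0, 2 * np.pi)
    raw = RawRecording(np.tile(x, (19, 1)), fs=fs, channel_labels=CHANNELS_1020)
    return raw, EventTable(pd.DataFrame(rows)), tracks
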
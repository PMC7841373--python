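"""Shared fixtures: simulated sessions reused across test modules."""

import dataclasses

import numpy as np
import pytest

from swimseg import SessionRecording, ImuRecording, SensorLocation
from swimseg.simulate import default_paper_config, simulate_session


@pytest.fixture(scope="session")
def paper_session():
    """One paper-default session (4 bouts × 2 laps, all techniques, noisy)."""
    return simulate_session(default_paper_config(seed=11))


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free paper-default session (deterministic templates only)."""
    cfg = dataclasses.replace(default_paper_config(seed=7),
                              noise_sd_acc=0.0, noise_sd_gyr=0.0)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def rest_only_session():
    """A session of quiet upright standing: no bouts anywhere."""
    rng = np.random.default_rng(0)
    n = 30 * 500
    recordings = {}
    for loc in SensorLocation:
        acc = np.zeros((n, 3))
        acc[:, 1] = 1.0
        acc += rng.normal(0, 0.05, acc.shape)
        gyr = rng.normal(0, 5.0, (n, 3))
        recordings[loc] = ImuRecording(acc=acc, gyr=gyr, fs=500.0,
                                       location=loc, frame="anatomical")
    return SessionRecording(recordings)
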
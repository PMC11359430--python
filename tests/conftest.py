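import dataclasses

import numpy as np
import pytest

from pulseaf.synth import AF_PRESET, NSR_PRESET, generate_record
from pulseaf.preprocess import preprocess_record, SegmentConfig


def noiseless(params, **overrides):
    """Rhythm params with measurement noise and baseline wander removed."""
    return dataclasses.replace(
        params, noise_sd=0.0, baseline_wander_amp=0.0, **overrides
    )


@pytest.fixture(scope="session")
def nsr_record():
    return generate_record(NSR_PRESET, duration_s=130, fs_hz=125, seed=11)


@pytest.fixture(scope="session")
def af_record():
    return generate_record(AF_PRESET, duration_s=130, fs_hz=125, seed=12)


@pytest.fixture(scope="session")
def nsr_segment(nsr_record):
    return preprocess_record(nsr_record, SegmentConfig())


@pytest.fixture(scope="session")
def two_tone():
    """The fixed two-tone signal used by the decomposition oracle tests."""
    fs = 125.0
    t = np.arange(1000) / fs
    hi = np.sin(2 * np.pi * 5.0 * t)
    lo = 0.8 * np.sin(2 * np.pi * 0.5 * t)
    return t, hi + lo, hi, lo
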
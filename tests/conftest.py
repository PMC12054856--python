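import numpy as np
import pandas as pd
import pytest

from tibhip.io import IntervalSet, MinuteSeries, RawTrace
from tibhip.synthetic import SimConfig, simulate_subject

NOON = pd.Timestamp("2024-03-04T12:00:00")


@pytest.fixture(scope="session")
def two_day_recording():
    """One simulated subject, two days at 1 Hz, default conditions."""
    return simulate_subject(SimConfig(n_subjects=1, days_per_subject=2, seed=11), 0)


@pytest.fixture(scope="session")
def miscalibrated_recording():
    cfg = SimConfig(
        n_subjects=1, days_per_subject=2, seed=13,
        miscalibration=((1.02, 1.0, 0.98), (0.03, 0.0, -0.02)),
    )
    return simulate_subject(cfg, 0)


@pytest.fixture
def constant_trace():
    """Two hours of a perfectly still device at 1 Hz."""
    samples = np.tile([0.0, 0.0, 1.0], (7200, 1))
    return RawTrace(NOON, 1.0, samples)


def make_series(values, labels=None, start=NOON, **kw):
    return MinuteSeries(start, np.asarray(values, dtype=float), labels=labels, **kw)


def make_intervals(*pairs):
    return IntervalSet.from_pairs(pairs)
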
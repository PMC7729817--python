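"""Shared fixtures: tiny synthetic cohorts reused across test modules."""

import numpy as np
import pytest

import gaitid as g


@pytest.fixture(scope="session")
def small_cohort():
    """Three easy subjects, 60 s at 50 Hz — enough for a handful of windows."""
    return g.simulate_cohort(3, 60.0, 50.0, seed=42, separability="easy")


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    return g.cohort_windows(small_cohort.recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, sensor="accelerometer", fs=50.0, subject="s0"):
    """Helper: wrap an (n, 3) array as a TriaxialSeries on a uniform grid."""
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / fs
    return g.TriaxialSeries(subject, sensor, fs, t, values)
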
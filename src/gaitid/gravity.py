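"""Orientation-invariant projection onto the estimated gravity axis.

A body-worn phone sits in an arbitrary, unknown orientation, so the raw
X/Y/Z axes mean nothing across recordings.  Gravity, however, dominates the
accelerometer's low-frequency content: the per-axis mean over a centred
sliding window approximates the (constant, sensor-frame) gravity vector.
Normalising that mean gives a per-sample unit gravity direction ĝ_t, and the
scalar product of the instantaneous sample with ĝ_t yields the vertical
acceleration acc_g (or, for the gyroscope, the vertical rotation rate w_g).
Because windowed means rotate covariantly and dot products are
rotation-invariant, the result is identical for any fixed device
orientation.

Defaults: half-window m = 150 samples (a 2m = 300-sample ≈ 6 s estimation
window at 50 Hz) and 150 samples (3 s) trimmed from each end, where the
subject is still starting or stopping and the signal is mostly noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateGravityError,
    DomainError,
    InsufficientDataError,
    UsageError,
)
from .sensor_io import TriaxialSeries

#: Default half-window m: 2m = 300 samples ≈ 6 s at 50 Hz.
DEFAULT_HALF_WINDOW = 150
#: Default number of samples trimmed from each end of the projected series (3 s at 50 Hz).
DEFAULT_TRIM = 150

Quantity = Literal["vertical_acceleration", "vertical_rotation"]


@dataclass
class MeanVectorTrack:
    """Per-sample windowed mean acceleration (x̄_m, ȳ_m, z̄_m)."""

    means: np.ndarray  # (n, 3)
    half_window_m: int

    def __len__(self) -> int:
        return len(self.means)


@dataclass
class GravityTrack:
    """Per-sample unit gravity directions ĝ_t in the sensor frame.

    ``source_sensor`` records which channel the estimate came from; vertical
    rotation must always use a gravity track estimated from the
    accelerometer.
    """

    unit_vectors: np.ndarray  # (n, 3), each unit norm
    half_window_m: int
    source_sensor: str = "accelerometer"

    def __len__(self) -> int:
        return len(self.unit_vectors)


@dataclass
class ScalarSeries:
    """A per-sample scalar channel: vertical acceleration or rotation."""

    values: np.ndarray  # (n,)
    quantity: Quantity
    subject_id: str
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DomainError(f"values must be 1-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("ScalarSeries values must all be finite")

    def __len__(self) -> int:
        return len(self.values)


def sliding_mean_vectors(series: TriaxialSeries, half_window_m: int = DEFAULT_HALF_WINDOW) -> MeanVectorTrack:
    """Centred sliding mean of the (x, y, z) samples.

    At index i the mean runs over indices [max(0, i−m), min(L−1, i+m)]
    inclusive; the window shrinks at the edges so the output has one triple
    per input sample.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot take sliding means of an empty series")
    if half_window_m < 1:
        raise DomainError(f"half_window_m must be >= 1, got {half_window_m}")
    n = len(series)
    m = half_window_m
    idx = np.arange(n)
    lo = np.maximum(0, idx - m)
    hi = np.minimum(n - 1, idx + m)
    csum = np.vstack([np.zeros(3), np.cumsum(series.samples, axis=0)])
    sums = csum[hi + 1] - csum[lo]
    means = sums / (hi - lo + 1)[:, None]
    return MeanVectorTrack(means=means, half_window_m=m)


def to_unit_gravity(track: MeanVectorTrack, *, source_sensor: str = "accelerometer",
                    min_norm: float = 1e-12) -> GravityTrack:
    """Normalise each windowed mean to a unit gravity direction ĝ."""
    norms = np.linalg.norm(track.means, axis=1)
    bad = np.nonzero(norms < min_norm)[0]
    if bad.size:
        raise DegenerateGravityError(int(bad[0]))
    return GravityTrack(
        unit_vectors=track.means / norms[:, None],
        half_window_m=track.half_window_m,
        source_sensor=source_sensor,
    )


def project_vertical_acceleration(series: TriaxialSeries, gravity: GravityTrack) -> ScalarSeries:
    """Scalar-project each acceleration sample onto its unit gravity vector:
    acc_g[i] = acc_i · ĝ_i.  The projection is signed; no absolute value."""
    if series.sensor != "accelerometer":
        raise UsageError("vertical acceleration requires an accelerometer series")
    if len(series) != len(gravity):
        raise AlignmentError(
            f"series length {len(series)} != gravity track length {len(gravity)}"
        )
    values = np.einsum("ij,ij->i", series.samples, gravity.unit_vectors)
    return ScalarSeries(values, "vertical_acceleration", series.subject_id,
                        series.sampling_rate_hz)


def project_vertical_rotation(gyro: TriaxialSeries, gravity: GravityTrack) -> ScalarSeries:
    """Scalar-project each angular-velocity sample onto ĝ: w_g[i] = w_i · ĝ_i.

    The gravity track must come from the time-aligned accelerometer stream of
    the same recording; gyroscope means carry no gravity information.
    """
    if gyro.sensor != "gyroscope":
        raise UsageError("vertical rotation requires a gyroscope series")
    if gravity.source_sensor != "accelerometer":
        raise UsageError("gravity for the gyroscope projection must be estimated "
                         "from the accelerometer channel")
    if len(gyro) != len(gravity):
        raise AlignmentError(
            f"gyro length {len(gyro)} != gravity track length {len(gravity)}"
        )
    values = np.einsum("ij,ij->i", gyro.samples, gravity.unit_vectors)
    return ScalarSeries(values, "vertical_rotation", gyro.subject_id,
                        gyro.sampling_rate_hz)


def trim_edges(series: ScalarSeries, trim_samples: int = DEFAULT_TRIM) -> ScalarSeries:
    """Drop ``trim_samples`` from each end (start/stop transients)."""
    if trim_samples < 0:
        raise DomainError(f"trim_samples must be >= 0, got {trim_samples}")
    if 2 * trim_samples >= len(series):
        raise InsufficientDataError(
            f"cannot trim {trim_samples} samples from each end of a "
            f"length-{len(series)} series"
        )
    if trim_samples == 0:
        values = series.values
    else:
        values = series.values[trim_samples:-trim_samples]
    return ScalarSeries(values, series.quantity, series.subject_id,
                        series.sampling_rate_hz)


def vertical_acceleration_pipeline(
    series: TriaxialSeries,
    half_window_m: int = DEFAULT_HALF_WINDOW,
    trim_samples: int = DEFAULT_TRIM,
) -> ScalarSeries:
    """Convenience chain: sliding means → unit gravity → projection → trim."""
    gravity = to_unit_gravity(sliding_mean_vectors(series, half_window_m))
    return trim_edges(project_vertical_acceleration(series, gravity), trim_samples)


def vertical_rotation_pipeline(
    acc: TriaxialSeries,
    gyro: TriaxialSeries,
    half_window_m: int = DEFAULT_HALF_WINDOW,
    trim_samples: int = DEFAULT_TRIM,
) -> ScalarSeries:
    """Gravity from the accelerometer, projection of the gyroscope, trim."""
    gravity = to_unit_gravity(sliding_mean_vectors(acc, half_window_m))
    return trim_edges(project_vertical_rotation(gyro, gravity), trim_samples)
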
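"""Reading, writing and resampling tri-axial inertial sensor logs.

A recording is a timestamped stream of (x, y, z) samples from one sensor
(accelerometer in m/s² or gyroscope in rad/s) worn by one subject.  Logs
arrive as CSV with a configurable column dialect; timestamps may be logged
in milliseconds or seconds and are stored internally in seconds.  Foreign
sampling rates (e.g. ~200 Hz phone sensors) are brought to the nominal
50 Hz grid by per-axis linear interpolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, InsufficientDataError, OrderingError

logger = logging.getLogger(__name__)

SensorKind = Literal["accelerometer", "gyroscope"]

#: Largest tolerated gap, as a multiple of the nominal sample period, before
#: a gap is reported in the load report (gaps are logged, never repaired).
GAP_FACTOR = 3.0


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for a sensor CSV export.

    ``timestamp_unit`` declares how the log's clock column is scaled;
    internally everything is seconds.
    """

    timestamp: str = "t"
    x: str = "x"
    y: str = "y"
    z: str = "z"
    timestamp_unit: Literal["ms", "s"] = "s"

    def required_columns(self) -> tuple[str, str, str, str]:
        return (self.timestamp, self.x, self.y, self.z)


#: Generic fallback dialect: columns t, x, y, z with timestamps in seconds.
DEFAULT_DIALECT = CsvDialect()

#: Dialect of "Sensor Data Collector"-style smartphone exports
#: (attr_time in milliseconds, attr_x/y/z).
SENSOR_DATA_COLLECTOR_DIALECT = CsvDialect(
    timestamp="attr_time", x="attr_x", y="attr_y", z="attr_z", timestamp_unit="ms"
)


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from one CSV load: rows dropped and gaps found."""

    n_rows_read: int
    n_rows_dropped_missing: int
    n_duplicate_timestamps_dropped: int
    gap_indices: tuple[int, ...] = ()


@dataclass
class TriaxialSeries:
    """One sensor channel of one subject: timestamps plus (x, y, z) samples.

    Invariants (enforced by :meth:`validate`): equal lengths, strictly
    increasing timestamps, positive sampling rate.
    """

    subject_id: str
    sensor: SensorKind
    sampling_rate_hz: float
    timestamps: np.ndarray  # (n,) seconds
    samples: np.ndarray  # (n, 3)
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"samples must be (n, 3), got shape {self.samples.shape}"
            )
        if len(self.timestamps) != len(self.samples):
            raise FormatError(
                f"{len(self.timestamps)} timestamps vs {len(self.samples)} samples"
            )
        if self.sensor not in ("accelerometer", "gyroscope"):
            raise FormatError(f"unknown sensor kind {self.sensor!r}")
        if not self.sampling_rate_hz > 0:
            raise DomainError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if len(self.timestamps) >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise OrderingError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


def read_triaxial_csv(
    path: str | Path,
    *,
    dialect: CsvDialect = DEFAULT_DIALECT,
    subject_id: str = "unknown",
    sensor: SensorKind = "accelerometer",
    drop_duplicate_timestamps: bool = True,
) -> TriaxialSeries:
    """Read a tri-axial sensor CSV into a validated :class:`TriaxialSeries`.

    Rows with missing values are dropped and counted in the load report.
    Duplicate timestamps are dropped with a logged warning (keeping the first
    occurrence); non-monotone timestamps otherwise raise :class:`OrderingError`.
    The sampling rate is estimated as (n − 1) / (t_last − t_first).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sensor log not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in dialect.required_columns() if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    n_read = len(frame)
    frame = frame[list(dialect.required_columns())].apply(pd.to_numeric, errors="coerce")
    frame = frame.dropna()
    n_dropped = n_read - len(frame)
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing values", path, n_dropped)

    t = frame[dialect.timestamp].to_numpy(dtype=float)
    if dialect.timestamp_unit == "ms":
        t = t / 1000.0
    xyz = frame[[dialect.x, dialect.y, dialect.z]].to_numpy(dtype=float)

    n_dup = 0
    if len(t) >= 2:
        keep = np.concatenate([[True], np.diff(t) > 0])
        if not keep.all():
            bad = ~keep
            if drop_duplicate_timestamps and np.all(np.diff(t)[bad[1:]] == 0):
                n_dup = int(bad.sum())
                logger.warning("%s: dropped %d duplicate timestamps", path, n_dup)
                t, xyz = t[keep], xyz[keep]
            else:
                raise OrderingError(f"{path}: timestamps are not strictly increasing")
    if len(t) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 valid rows ({len(t)})")

    rate = (len(t) - 1) / (t[-1] - t[0])
    period = 1.0 / rate
    gaps = tuple(int(i) for i in np.nonzero(np.diff(t) > GAP_FACTOR * period)[0])
    if gaps:
        logger.warning("%s: %d timestamp gaps > %.0f periods (logged, not repaired)",
                       path, len(gaps), GAP_FACTOR)
    report = LoadReport(n_read, n_dropped, n_dup, gaps)
    return TriaxialSeries(subject_id, sensor, rate, t, xyz, load_report=report)


def write_triaxial_csv(series: TriaxialSeries, path: str | Path) -> Path:
    """Write a series as CSV (header t,x,y,z; seconds; full float precision).

    :func:`read_triaxial_csv` with the default dialect inverts this exactly.
    """
    if len(series) == 0:
        raise InsufficientDataError("refusing to write an empty series")
    path = Path(path)
    data = np.column_stack([series.timestamps, series.samples])
    with open(path, "w") as handle:
        handle.write("t,x,y,z\n")
        # %.17g round-trips float64 exactly
        np.savetxt(handle, data, fmt="%.17g", delimiter=",")
    return path


def resample_to_rate(series: TriaxialSeries, target_hz: float) -> TriaxialSeries:
    """Linearly interpolate each axis onto a uniform grid at ``target_hz``.

    The grid spans [t_first, t_last] with spacing 1/target_hz; affine signals
    are reproduced exactly (up to float rounding).
    """
    if target_hz <= 0:
        raise DomainError(f"target_hz must be positive, got {target_hz}")
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    n_out = int(math.floor((t1 - t0) * target_hz + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / target_hz
    out = np.column_stack(
        [np.interp(grid, series.timestamps, series.samples[:, k]) for k in range(3)]
    )
    return replace(series, sampling_rate_hz=float(target_hz), timestamps=grid,
                   samples=out, load_report=None)
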
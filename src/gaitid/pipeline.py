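"""End-to-end glue: raw recordings → projected scalar series → window sets.

These helpers chain the preprocessing stages with their study defaults
(resample to 50 Hz if needed, 2m = 300-sample gravity window, 3 s edge
trim, 150-sample windows with half-segment overlap) so that the evaluation
protocols, CLI and examples all run the identical pipeline.
"""

from __future__ import annotations

from .errors import AlignmentError
from .gravity import (
    DEFAULT_HALF_WINDOW,
    DEFAULT_TRIM,
    ScalarSeries,
    sliding_mean_vectors,
    to_unit_gravity,
    project_vertical_acceleration,
    project_vertical_rotation,
    trim_edges,
)
from .sensor_io import TriaxialSeries, resample_to_rate
from .windowing import DEFAULT_WINDOW_LEN, WindowSet, make_windows, merge_cohorts

NOMINAL_RATE_HZ = 50.0


def preprocess_recording(
    acc: TriaxialSeries,
    gyro: TriaxialSeries | None = None,
    *,
    half_window_m: int = DEFAULT_HALF_WINDOW,
    trim_samples: int = DEFAULT_TRIM,
    target_hz: float | None = None,
) -> list[ScalarSeries]:
    """One subject's recording → [acc_g] or [acc_g, w_g].

    If ``target_hz`` is given both channels are first resampled onto that
    uniform grid.  Gravity is always estimated from the accelerometer and
    shared with the gyroscope projection.
    """
    if target_hz is not None:
        acc = resample_to_rate(acc, target_hz)
        gyro = resample_to_rate(gyro, target_hz) if gyro is not None else None
    if gyro is not None and len(gyro) != len(acc):
        # resampling both onto [t_first, t_last] grids can differ by one
        # sample on jittered clocks; align on the common prefix
        n = min(len(acc), len(gyro))
        if abs(len(acc) - len(gyro)) > 2:
            raise AlignmentError(
                f"accelerometer ({len(acc)}) and gyroscope ({len(gyro)}) lengths "
                "differ by more than resampling edge effects"
            )
        acc = TriaxialSeries(acc.subject_id, acc.sensor, acc.sampling_rate_hz,
                             acc.timestamps[:n], acc.samples[:n])
        gyro = TriaxialSeries(gyro.subject_id, gyro.sensor, gyro.sampling_rate_hz,
                              gyro.timestamps[:n], gyro.samples[:n])
    gravity = to_unit_gravity(sliding_mean_vectors(acc, half_window_m))
    out = [trim_edges(project_vertical_acceleration(acc, gravity), trim_samples)]
    if gyro is not None:
        out.append(trim_edges(project_vertical_rotation(gyro, gravity), trim_samples))
    return out


def cohort_windows(
    recordings: list[tuple[TriaxialSeries, TriaxialSeries | None]],
    *,
    use_gyro: bool = False,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int | None = None,
    half_window_m: int = DEFAULT_HALF_WINDOW,
    trim_samples: int = DEFAULT_TRIM,
    target_hz: float | None = None,
) -> WindowSet:
    """Preprocess and window a whole cohort into one labelled WindowSet.

    Subjects are labelled 0..K−1 in recording order.
    """
    per_subject = []
    for acc, gyro in recordings:
        series = preprocess_recording(
            acc, gyro if use_gyro else None,
            half_window_m=half_window_m, trim_samples=trim_samples,
            target_hz=target_hz,
        )
        per_subject.append(make_windows(series, window_len=window_len, stride=stride))
    return merge_cohorts(per_subject)


def cohort_scalar_series(
    recordings: list[tuple[TriaxialSeries, TriaxialSeries | None]],
    *,
    use_gyro: bool = False,
    half_window_m: int = DEFAULT_HALF_WINDOW,
    trim_samples: int = DEFAULT_TRIM,
    target_hz: float | None = None,
) -> list[list[ScalarSeries]]:
    """Preprocess a cohort but stop before windowing (one feature list per
    subject) — the input shape the window-size sweep re-windows from."""
    return [
        preprocess_recording(acc, gyro if use_gyro else None,
                             half_window_m=half_window_m,
                             trim_samples=trim_samples, target_hz=target_hz)
        for acc, gyro in recordings
    ]


def windows_from_series(
    corpus: list[list[ScalarSeries]],
    *,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int | None = None,
) -> WindowSet:
    """Window an already-preprocessed corpus (one feature list per subject)."""
    per_subject = [
        make_windows(series, window_len=window_len, stride=stride)
        for series in corpus
    ]
    return merge_cohorts(per_subject)
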
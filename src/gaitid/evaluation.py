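"""Scoring and experiment protocols for the gait identifier.

Accuracy here is closed-set categorical accuracy (fraction of test windows
assigned to the right subject), reported in [0, 1] internally and formatted
as a percentage only at presentation.  The experiment protocols mirror the
study designs: repeated runs over a group of split seeds (mean and
population variance per group), an accelerometer/gyroscope/fused ablation
on one shared test partition, and a window-size sweep that re-windows the
corpus and resizes the network for each window length.

Experiment tables are plain pandas DataFrames (one row per condition) so
they serialise to CSV losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError
from .gravity import ScalarSeries
from .model import (
    ArchConfig,
    FitResult,
    GaitClassifier,
    TrainConfig,
    default_input_shift,
    train_model,
)
from .windowing import WindowSet, split_train_test
from . import pipeline

logger = logging.getLogger(__name__)


def compute_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1 or len(predicted) == 0:
        raise AlignmentError(
            f"need two equal-length label sequences, got {predicted.shape} "
            f"and {truth.shape}"
        )
    return float(np.mean(predicted == truth))


def confusion_matrix(predicted: np.ndarray, truth: np.ndarray, n_classes: int
                     ) -> np.ndarray:
    """K × K counts; entry (i, j) = windows of true class i predicted as j."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise AlignmentError("predicted and truth differ in length")
    for name, arr in (("predicted", predicted), ("truth", truth)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise DomainError(f"{name} labels out of range [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (truth, predicted), 1)
    return mat


@dataclass
class EvalReport:
    """Test-set performance of one trained model."""

    accuracy: float
    confusion: np.ndarray
    n_test: int
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.confusion.sum() == self.n_test
        assert abs(np.trace(self.confusion) / self.n_test - self.accuracy) < 1e-12

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.label_names),
                            columns=list(self.label_names))


def evaluate_model(model: GaitClassifier, test: WindowSet) -> EvalReport:
    """Score a trained model on held-out windows."""
    predicted = model.identify(test)
    acc = compute_accuracy(predicted, test.labels)
    mat = confusion_matrix(predicted, test.labels, test.n_classes)
    return EvalReport(accuracy=acc, confusion=mat, n_test=len(test),
                      label_names=test.label_names)


def _run_once(windows: WindowSet, arch: ArchConfig, train_config: TrainConfig,
              split_seed: int, test_fraction: float) -> tuple[EvalReport, FitResult]:
    split = split_train_test(windows, test_fraction, split_seed)
    model = GaitClassifier(arch, seed=train_config.seed,
                           input_shift=default_input_shift(windows.feature_names))
    fit = train_model(model, split.train, config=train_config)
    return evaluate_model(fit.model, split.test), fit


def seeded_repeats(
    windows: WindowSet,
    arch: ArchConfig,
    train_config: TrainConfig,
    seeds: list[int],
    *,
    repeats: int = 3,
    test_fraction: float = 0.3,
    vary_training_seed: bool = True,
) -> pd.DataFrame:
    """Repeated train/test runs per split seed.

    One row per seed with the per-run accuracies, their mean, and the
    population variance within the group.  ``vary_training_seed=True`` gives
    each repeat its own weight-init/shuffle seed ("different executions");
    with ``False`` every repeat is bit-identical and the variance is 0.
    """
    if not seeds:
        raise DomainError("need at least one split seed")
    rows = []
    for seed in seeds:
        accs = []
        for r in range(repeats):
            cfg = (replace(train_config, seed=train_config.seed + 1000 * r + seed)
                   if vary_training_seed else train_config)
            report, _ = _run_once(windows, arch, cfg, seed, test_fraction)
            accs.append(report.accuracy)
        rows.append({
            "seed": seed,
            **{f"accuracy_run{r + 1}": a for r, a in enumerate(accs)},
            "mean_accuracy": float(np.mean(accs)),
            "variance": float(np.var(accs)),  # population variance over the group
        })
    return pd.DataFrame(rows)


def sensor_ablation(
    acc_windows: WindowSet,
    gyro_windows: WindowSet,
    arch: ArchConfig,
    train_config: TrainConfig,
    *,
    split_seed: int = 0,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Accelerometer-only vs gyroscope-only vs fused, on one test partition.

    The two window sets must be window-aligned (same subjects, same window
    layout); the fused condition concatenates them on the feature axis, and
    all three models are trained and scored on the identical split indices.
    """
    if (len(acc_windows) != len(gyro_windows)
            or acc_windows.window_len != gyro_windows.window_len
            or not np.array_equal(acc_windows.labels, gyro_windows.labels)
            or acc_windows.label_names != gyro_windows.label_names):
        raise AlignmentError("accelerometer and gyroscope window sets are not aligned")
    fused = WindowSet(
        np.concatenate([acc_windows.windows, gyro_windows.windows], axis=2),
        acc_windows.labels, acc_windows.label_names,
        acc_windows.feature_names + gyro_windows.feature_names,
        acc_windows.window_len, acc_windows.stride,
    )
    conditions = [
        ("acceleration only", acc_windows),
        ("gyroscope only", gyro_windows),
        ("both sensors", fused),
    ]
    rows = []
    for name, ws in conditions:
        cond_arch = replace(arch, n_features=ws.n_features,
                            window_len=ws.window_len, n_classes=ws.n_classes)
        report, _ = _run_once(ws, cond_arch, train_config, split_seed, test_fraction)
        rows.append({
            "condition": name,
            "n_features": ws.n_features,
            "n_train": len(ws) - report.n_test,
            "n_test": report.n_test,
            "accuracy": report.accuracy,
        })
    return pd.DataFrame(rows)


def window_size_sweep(
    corpus: list[list[ScalarSeries]],
    sizes: list[int],
    arch_template: ArchConfig,
    train_config: TrainConfig,
    *,
    split_seed: int = 0,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Re-window, resize the network, retrain and score for each window size.

    For each size T the corpus is re-windowed with stride ⌊T/2⌋, split with
    the same seed (re-windowing changes n, so the partition is redrawn), and
    an architecture with window_len = T is trained.  Sizes longer than the
    shortest subject series are skipped with a warning.
    """
    fs = corpus[0][0].sampling_rate_hz
    shortest = min(len(series[0]) for series in corpus)
    rows = []
    for size in sizes:
        if size < 2:
            raise DomainError(f"window size must be >= 2 samples, got {size}")
        if size > shortest:
            logger.warning("window size %d exceeds shortest series (%d); row skipped",
                           size, shortest)
            continue
        windows = pipeline.windows_from_series(corpus, window_len=size)
        arch = replace(arch_template, window_len=size,
                       n_features=windows.n_features, n_classes=windows.n_classes)
        report, _ = _run_once(windows, arch, train_config, split_seed, test_fraction)
        rows.append({
            "window_len": size,
            "duration_s": size / fs,
            "n_train": len(windows) - report.n_test,
            "n_test": report.n_test,
            "accuracy": report.accuracy,
        })
    return pd.DataFrame(rows)
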
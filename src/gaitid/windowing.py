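"""Fixed-length window packaging, label encoding and train/test splitting.

A classifier input is a window of T consecutive scalar samples (default
T = 150, i.e. 3 s at 50 Hz) with F feature channels (vertical acceleration
alone, or acceleration + rotation for sensor fusion).  Consecutive windows
overlap by half a segment by default (stride = T // 2); trailing partial
windows are discarded.  Labels are integer subject indices, one-hot encoded
for training, and the window set is split 70/30 by a seeded uniform random
permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DomainError, IdentityError, SplitError
from .gravity import ScalarSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 150
DEFAULT_TEST_FRACTION = 0.3


@dataclass
class WindowSet:
    """n windows of shape T × F with integer subject labels in [0, K)."""

    windows: np.ndarray  # (n, T, F)
    labels: np.ndarray  # (n,)
    label_names: tuple[str, ...]  # K subject ids, index == label
    feature_names: tuple[str, ...]  # F channel names
    window_len: int
    stride: int

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise DomainError(f"windows must be (n, T, F), got {self.windows.shape}")
        if len(self.windows) != len(self.labels):
            raise AlignmentError("windows and labels differ in length")
        if self.windows.shape[1] != self.window_len:
            raise AlignmentError("window tensor T does not match window_len")
        if len(set(self.label_names)) != len(self.label_names):
            raise IdentityError("duplicate subject ids in label_names")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise DomainError("labels out of range [0, K)")
        if not np.all(np.isfinite(self.windows)):
            raise DomainError("windows contain non-finite values")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    @property
    def n_features(self) -> int:
        return self.windows.shape[2]

    def subset(self, indices: np.ndarray) -> "WindowSet":
        return WindowSet(self.windows[indices], self.labels[indices],
                         self.label_names, self.feature_names,
                         self.window_len, self.stride)


@dataclass
class OneHotLabels:
    """n × K one-hot label matrix; each row has exactly one 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class SplitResult:
    train: WindowSet
    test: WindowSet
    seed: int
    test_fraction: float


def count_windows(series_len: int, window_len: int, stride: int) -> int:
    """Number of full windows: floor((L − T)/stride) + 1, or 0 if L < T."""
    if window_len < 1 or stride < 1:
        raise DomainError("window_len and stride must be >= 1")
    if series_len < window_len:
        return 0
    return (series_len - window_len) // stride + 1


def make_windows(
    series_by_feature: list[ScalarSeries],
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int | None = None,
    label: int = 0,
    label_names: tuple[str, ...] | None = None,
) -> WindowSet:
    """Package time-aligned feature series of one subject into windows.

    Window i covers sample indices [i·stride, i·stride + T); windows are in
    start-time order and all carry ``label``.  A series shorter than one
    window yields an empty set with a logged warning.
    """
    if not series_by_feature:
        raise DomainError("need at least one feature series")
    if stride is None:
        stride = max(1, window_len // 2)
    lengths = {len(s) for s in series_by_feature}
    if len(lengths) != 1:
        raise AlignmentError(f"feature series have unequal lengths {sorted(lengths)}")
    (length,) = lengths
    subject = series_by_feature[0].subject_id
    if label_names is None:
        label_names = (subject,)
    feature_names = tuple(s.quantity for s in series_by_feature)

    n = count_windows(length, window_len, stride)
    if n == 0:
        logger.warning("subject %s: series of length %d shorter than window %d; "
                       "0 windows produced", subject, length, window_len)
    starts = np.arange(n) * stride
    data = np.stack([s.values for s in series_by_feature], axis=1)  # (L, F)
    windows = np.stack([data[s : s + window_len] for s in starts], axis=0) if n else \
        np.empty((0, window_len, len(series_by_feature)))
    labels = np.full(n, label, dtype=int)
    return WindowSet(windows, labels, label_names, feature_names, window_len, stride)


def encode_one_hot(labels: np.ndarray, n_classes: int) -> OneHotLabels:
    """Integer labels → n × K one-hot matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise DomainError(f"labels must lie in [0, {n_classes})")
    matrix = np.zeros((len(labels), n_classes))
    matrix[np.arange(len(labels)), labels] = 1.0
    return OneHotLabels(matrix)


def decode_one_hot(onehot: OneHotLabels) -> np.ndarray:
    """Inverse of :func:`encode_one_hot`: index of the 1 in each row."""
    return np.argmax(onehot.matrix, axis=1)


def split_train_test(
    windows: WindowSet,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> SplitResult:
    """Seeded uniform random 70/30-style split of windows.

    Test size is round(n · test_fraction) (round-half-even); the same seed
    always produces the same partition; train and test are disjoint and
    together exhaust the set.
    """
    if not 0 < test_fraction < 1:
        raise DomainError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(windows)
    n_test = round(n * test_fraction)
    if n_test == 0 or n_test == n:
        raise SplitError(f"split of n={n} at fraction {test_fraction} leaves an "
                         "empty train or test side")
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    for name, side in (("train", train_idx), ("test", test_idx)):
        counts = np.bincount(windows.labels[side], minlength=windows.n_classes)
        logger.debug("split seed=%d %s per-class counts: %s", seed, name, counts.tolist())
    return SplitResult(windows.subset(train_idx), windows.subset(test_idx),
                       seed, test_fraction)


def split_train_test_blocked(
    windows: WindowSet,
    test_fraction: float = DEFAULT_TEST_FRACTION,
) -> SplitResult:
    """Contiguous (time-blocked) split: per class, the last fraction of
    windows in start-time order becomes the test side.

    Overlapping windows share samples, so the default i.i.d. split leaks
    test information into training; this variant avoids that at the cost of
    a non-random partition.
    """
    if not 0 < test_fraction < 1:
        raise DomainError(f"test_fraction must be in (0, 1), got {test_fraction}")
    train_parts, test_parts = [], []
    for k in range(windows.n_classes):
        idx = np.nonzero(windows.labels == k)[0]
        n_test = round(len(idx) * test_fraction)
        train_parts.append(idx[: len(idx) - n_test])
        test_parts.append(idx[len(idx) - n_test :])
    train_idx = np.concatenate(train_parts)
    test_idx = np.concatenate(test_parts)
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise SplitError("blocked split leaves an empty side")
    return SplitResult(windows.subset(train_idx), windows.subset(test_idx),
                       -1, test_fraction)


def merge_cohorts(sets: list[WindowSet]) -> WindowSet:
    """Concatenate window sets, relabelling subjects onto [0, K_total).

    Per-set subject identity is preserved (labels are offset by the running
    class count); duplicate subject ids across sets are an error.
    """
    if not sets:
        raise DomainError("nothing to merge")
    first = sets[0]
    for other in sets[1:]:
        if (other.window_len != first.window_len
                or other.windows.shape[2] != first.windows.shape[2]
                or other.feature_names != first.feature_names):
            raise AlignmentError("window sets differ in T, F or feature names")
    all_names: list[str] = []
    windows, labels = [], []
    offset = 0
    for ws in sets:
        dupes = set(ws.label_names) & set(all_names)
        if dupes:
            raise IdentityError(f"duplicate subject ids across cohorts: {sorted(dupes)}")
        all_names.extend(ws.label_names)
        windows.append(ws.windows)
        labels.append(ws.labels + offset)
        offset += ws.n_classes
    return WindowSet(np.concatenate(windows), np.concatenate(labels),
                     tuple(all_names), first.feature_names,
                     first.window_len, first.stride)
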
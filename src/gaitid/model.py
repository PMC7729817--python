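"""The stacked-LSTM gait identifier.

Architecture: two LSTM layers (the first emitting per-timestep outputs to
feed the second, the second emitting only its final state), a stack of
fully connected ReLU layers, and a softmax output with one neuron per
subject.  Training minimises categorical cross-entropy with Adam.

Five named presets ID1..ID5 cover the studied architecture grid, all with
150-sample single-channel input windows and 15 output classes:

    ====  ===========  ==============  ==================
    name  LSTM units   dense widths    trainable params
    ====  ===========  ==============  ==================
    ID1   50, 100      100, 90         91,355
    ID2   50, 100      100, 60         87,875
    ID3   50, 100      100, 90, 60     96,365
    ID4   50, 100      100, 60, 30     89,255
    ID5   100, 100     100, 90         141,755
    ====  ===========  ==============  ==================

The parameter count is architecture-only (independent of the window length
T): an LSTM layer with input width d and h units has 4·(h·(d+h) + h)
weights; a dense layer d → h has d·h + h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DivergenceError, DomainError
from .nn import Adam, DenseLayer, LSTMLayer, softmax_cross_entropy
from .windowing import OneHotLabels, WindowSet, encode_one_hot


@dataclass(frozen=True)
class ArchConfig:
    """Hyperparameters defining one identifier architecture."""

    window_len: int = 150
    n_features: int = 1
    lstm_units: tuple[int, int] = (50, 100)
    dense_units: tuple[int, ...] = (100, 90)
    n_classes: int = 15

    def __post_init__(self) -> None:
        counts = (self.window_len, self.n_features, *self.lstm_units,
                  *self.dense_units, self.n_classes)
        if any(c < 1 for c in counts):
            raise DomainError("all architecture sizes must be >= 1")
        if len(self.lstm_units) != 2:
            raise DomainError("the identifier stacks exactly two LSTM layers")


#: The studied architecture grid (single-channel 150-sample windows, 15 subjects).
PRESETS: dict[str, ArchConfig] = {
    "ID1": ArchConfig(lstm_units=(50, 100), dense_units=(100, 90)),
    "ID2": ArchConfig(lstm_units=(50, 100), dense_units=(100, 60)),
    "ID3": ArchConfig(lstm_units=(50, 100), dense_units=(100, 90, 60)),
    "ID4": ArchConfig(lstm_units=(50, 100), dense_units=(100, 60, 30)),
    "ID5": ArchConfig(lstm_units=(100, 100), dense_units=(100, 90)),
}


def preset(name: str, **overrides) -> ArchConfig:
    """Look up a named preset, optionally overriding fields
    (e.g. ``preset("ID5", n_features=2)`` for the two-sensor variant)."""
    if name not in PRESETS:
        raise DomainError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def count_trainable_params(config: ArchConfig) -> int:
    """Analytic trainable-parameter count of the architecture.

    LSTM (input d, units h): 4·(h·(d+h) + h); dense d → h: d·h + h.
    Independent of the window length.
    """
    total = 0
    d = config.n_features
    for h in config.lstm_units:
        total += 4 * (h * (d + h) + h)
        d = h
    for h in (*config.dense_units, config.n_classes):
        total += d * h + h
        d = h
    return total


#: Standard gravity, m/s² — the known DC component of vertical acceleration.
STANDARD_GRAVITY = 9.81


def default_input_shift(feature_names: tuple[str, ...]) -> tuple[float, ...]:
    """Physics-derived input conditioning constants, one per feature channel.

    Vertical acceleration oscillates about standard gravity; a constant
    +g offset at the LSTM input saturates the gates at initialisation and
    stalls training, so the classifier subtracts g before the recurrence
    (an exact reparameterisation of the first layer's bias initialisation —
    the window data themselves stay raw).  Vertical rotation is zero-mean
    by construction and is not shifted; unknown channels default to 0.
    """
    return tuple(
        STANDARD_GRAVITY if name == "vertical_acceleration" else 0.0
        for name in feature_names
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (Adam + categorical cross-entropy)."""

    epochs: int = 75
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    validation_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise DomainError("epochs and batch_size must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise DomainError("validation_fraction must be in [0, 1)")


class GaitClassifier:
    """A built (possibly trained) stacked-LSTM identifier."""

    def __init__(self, config: ArchConfig, *, seed: int = 0, dtype=np.float32,
                 input_shift: tuple[float, ...] | None = None):
        self.config = config
        self.dtype = dtype
        if input_shift is None:
            input_shift = (0.0,) * config.n_features
        if len(input_shift) != config.n_features:
            raise ConfigurationError(
                f"input_shift has {len(input_shift)} entries for "
                f"{config.n_features} features")
        # constant per-feature input conditioning (see default_input_shift);
        # equivalent to re-initialising the first layer's bias as b − s·W
        self.input_shift = np.asarray(input_shift, dtype=dtype)
        rng = np.random.default_rng(seed)
        self.layers: list[LSTMLayer | DenseLayer] = [
            LSTMLayer(config.n_features, config.lstm_units[0],
                      return_sequences=True, rng=rng, dtype=dtype),
            LSTMLayer(config.lstm_units[0], config.lstm_units[1],
                      return_sequences=False, rng=rng, dtype=dtype),
        ]
        d = config.lstm_units[1]
        for h in config.dense_units:
            self.layers.append(DenseLayer(d, h, activation="relu", rng=rng, dtype=dtype))
            d = h
        self.layers.append(DenseLayer(d, config.n_classes, activation="linear",
                                      rng=rng, dtype=dtype))

    # -- introspection -----------------------------------------------------

    def layer_manifest(self) -> list[dict]:
        """One entry per layer: kind, input/output widths, parameter count."""
        manifest = []
        d = self.config.n_features
        for layer in self.layers:
            if isinstance(layer, LSTMLayer):
                entry = {"kind": "lstm", "input_width": d, "output_width": layer.units,
                         "return_sequences": layer.return_sequences,
                         "n_params": layer.n_params()}
                d = layer.units
            else:
                out = layer.W.shape[1]
                entry = {"kind": f"dense_{layer.activation}"
                         if layer.activation == "relu" else "dense_softmax",
                         "input_width": d, "output_width": out,
                         "n_params": layer.n_params()}
                d = out
            manifest.append(entry)
        return manifest

    def n_trainable_params(self) -> int:
        """Actual tally of weights held by the built layers."""
        return sum(layer.n_params() for layer in self.layers)

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, *, cache: bool) -> np.ndarray:
        out = np.asarray(X, dtype=self.dtype)
        if self.input_shift.any():
            out = out - self.input_shift
        for layer in self.layers:
            out = layer.forward(out, cache=cache)
        return out  # logits

    def _backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _check_shapes(self, windows: WindowSet) -> None:
        cfg = self.config
        if windows.window_len != cfg.window_len or windows.n_features != cfg.n_features:
            raise ConfigurationError(
                f"windows are T={windows.window_len}, F={windows.n_features} but the "
                f"model expects T={cfg.window_len}, F={cfg.n_features}"
            )

    # -- inference ---------------------------------------------------------

    def predict_proba(self, windows: WindowSet, *, batch_size: int = 256) -> np.ndarray:
        """Per-window categorical probabilities (n × K; rows sum to 1)."""
        self._check_shapes(windows)
        from .nn import softmax

        probs = []
        for start in range(0, len(windows), batch_size):
            logits = self._forward(windows.windows[start : start + batch_size],
                                   cache=False)
            probs.append(softmax(logits.astype(np.float64)))
        return np.concatenate(probs) if probs else np.empty((0, self.config.n_classes))

    def identify(self, windows: WindowSet) -> np.ndarray:
        """Hard subject assignment: argmax probability, ties to lowest index."""
        return np.argmax(self.predict_proba(windows), axis=1)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li}_p{pi}"] = p
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "arch": {
                "window_len": self.config.window_len,
                "n_features": self.config.n_features,
                "lstm_units": list(self.config.lstm_units),
                "dense_units": list(self.config.dense_units),
                "n_classes": self.config.n_classes,
            },
            "input_shift": self.input_shift.tolist(),
            "manifest": self.layer_manifest(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "GaitClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        arch = meta["arch"]
        config = ArchConfig(
            window_len=arch["window_len"], n_features=arch["n_features"],
            lstm_units=tuple(arch["lstm_units"]),
            dense_units=tuple(arch["dense_units"]), n_classes=arch["n_classes"],
        )
        model = cls(config, input_shift=tuple(meta.get("input_shift", [])) or None)
        with np.load(directory / "weights.npz") as data:
            for li, layer in enumerate(model.layers):
                for pi, p in enumerate(layer.params):
                    p[:] = data[f"layer{li}_p{pi}"]
        return model


def build_architecture(config: ArchConfig, *, seed: int = 0,
                       input_shift: tuple[float, ...] | None = None
                       ) -> tuple[GaitClassifier, list[dict]]:
    """Instantiate the identifier and return it with its layer manifest."""
    model = GaitClassifier(config, seed=seed, input_shift=input_shift)
    return model, model.layer_manifest()


@dataclass
class FitResult:
    """Trained model plus per-epoch history (train/validation loss+accuracy)."""

    model: GaitClassifier
    history: dict[str, list[float]] = field(default_factory=dict)


def train_model(
    model: GaitClassifier,
    train: WindowSet,
    labels: OneHotLabels | None = None,
    config: TrainConfig = TrainConfig(),
) -> FitResult:
    """Train with Adam on categorical cross-entropy.

    A validation split (``config.validation_fraction`` of the training
    windows, seeded) is carved off before fitting and never trained on.
    Per-epoch train metrics are running averages over the epoch's
    minibatches; validation metrics are computed after each epoch.  The same
    seed and data reproduce the history exactly.
    """
    model._check_shapes(train)
    if labels is None:
        labels = encode_one_hot(train.labels, model.config.n_classes)
    Y = labels.matrix
    if Y.shape != (len(train), model.config.n_classes):
        raise ConfigurationError(
            f"one-hot labels of shape {Y.shape} do not match "
            f"({len(train)}, {model.config.n_classes})"
        )
    rng = np.random.default_rng(config.seed)

    n = len(train)
    n_val = round(n * config.validation_fraction)
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    X_fit = train.windows[fit_idx].astype(model.dtype)
    X_val = train.windows[val_idx].astype(model.dtype)
    Y_fit, Y_val = Y[fit_idx], Y[val_idx]
    if config.batch_size > len(X_fit):
        raise ConfigurationError(
            f"batch_size {config.batch_size} exceeds the {len(X_fit)} training "
            "windows left after the validation split"
        )

    params = [p for layer in model.layers for p in layer.params]
    optimiser = Adam(params, config.learning_rate, config.beta1, config.beta2)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_fit))
        losses, hits, seen = 0.0, 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            logits = model._forward(X_fit[batch], cache=True)
            loss, probs, dlogits = softmax_cross_entropy(logits, Y_fit[batch])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model._backward(dlogits)
            optimiser.step([g for layer in model.layers for g in layer.grads])
            losses += loss * len(batch)
            hits += int((probs.argmax(1) == Y_fit[batch].argmax(1)).sum())
            seen += len(batch)
        history["loss"].append(losses / seen)
        history["accuracy"].append(hits / seen)
        if n_val:
            logits = model._forward(X_val, cache=False)
            val_loss, val_probs, _ = softmax_cross_entropy(logits, Y_val)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(
                float((val_probs.argmax(1) == Y_val.argmax(1)).mean()))
        else:
            history["val_loss"].append(float("nan"))
            history["val_accuracy"].append(float("nan"))
    return FitResult(model=model, history=history)
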
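"""Minimal dense/LSTM neural-network layers in pure numpy.

This module implements exactly what the gait identifier needs and nothing
more: an LSTM layer (per-timestep or final-state output), a dense layer with
ReLU or linear activation, a fused softmax + categorical cross-entropy head,
and the Adam optimiser.  Everything is float64 and seeded, so training is
bit-reproducible on a given platform.

Conventions match the common deep-learning libraries so that analytic
parameter counts carry over: an LSTM layer with input width d and h memory
units holds an input kernel W (d × 4h), a recurrent kernel U (h × 4h) and a
bias (4h,), i.e. 4·(h·(d+h) + h) trainable scalars, with gate order
[input i, forget f, candidate g, output o]:

    z_t = x_t W + h_{t−1} U + b
    i, f, o = σ(z_i), σ(z_f), σ(z_o);  g = tanh(z_g)
    c_t = f ∘ c_{t−1} + i ∘ g;         h_t = o ∘ tanh(c_t)

Initialisation: Glorot-uniform input/dense kernels (fans taken from the
full kernel shape), row-orthonormal recurrent kernels, zero biases with the
forget-gate bias set to 1.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow warnings for large |x|
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Semi-orthogonal (rows, cols) matrix: orthonormal rows if rows <= cols."""
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q.T if rows < cols else q[:rows, :cols]


class LSTMLayer:
    """One LSTM layer over (N, T, d) inputs.

    ``return_sequences=True`` emits the hidden state at every timestep
    (N, T, h); otherwise only the final hidden state (N, h).
    """

    def __init__(self, input_dim: int, units: int, *, return_sequences: bool,
                 rng: np.random.Generator, dtype=np.float32):
        d, h = input_dim, units
        self.input_dim, self.units = d, h
        self.return_sequences = return_sequences
        self.dtype = dtype
        # fans follow the full kernel shape (d, 4h), matching the common
        # backend convention; the recurrent kernel is row-orthonormal
        self.W = _glorot_uniform(rng, d, 4 * h, (d, 4 * h)).astype(dtype)
        self.U = _orthogonal(rng, h, 4 * h).astype(dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self._cache: dict | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.dU, self.db]

    def n_params(self) -> int:
        return self.W.size + self.U.size + self.b.size

    def forward(self, X: np.ndarray, *, cache: bool = True) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=self.dtype)
        N, T, d = X.shape
        h = self.units
        H = np.zeros((T, N, h), dtype=self.dtype)
        gates = np.zeros((T, N, 4 * h), dtype=self.dtype) if cache else None
        C = np.zeros((T, N, h), dtype=self.dtype) if cache else None
        h_t = np.zeros((N, h), dtype=self.dtype)
        c_t = np.zeros((N, h), dtype=self.dtype)
        xW = (X.reshape(N * T, d) @ self.W).reshape(N, T, 4 * h) + self.b
        for t in range(T):
            z = xW[:, t, :] + h_t @ self.U
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_t = f * c_t + i * g
            h_t = o * np.tanh(c_t)
            H[t] = h_t
            if cache:
                gt = gates[t]
                gt[:, :h] = i
                gt[:, h : 2 * h] = f
                gt[:, 2 * h : 3 * h] = g
                gt[:, 3 * h :] = o
                C[t] = c_t
        if cache:
            self._cache = {"X": X, "H": H, "gates": gates, "C": C}
        return H.transpose(1, 0, 2) if self.return_sequences else H[-1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop-through-time; accumulates kernel grads, returns dX."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        X, H, gates, C = cache["X"], cache["H"], cache["gates"], cache["C"]
        N, T, d = X.shape
        h = self.units
        dout = np.asarray(dout, dtype=self.dtype)
        if self.return_sequences:
            dH = dout.transpose(1, 0, 2)  # (T, N, h)
        else:
            dH = np.zeros((T, N, h), dtype=self.dtype)
            dH[-1] = dout
        dZ = np.empty((T, N, 4 * h), dtype=self.dtype)
        dh_next = np.zeros((N, h), dtype=self.dtype)
        dc_next = np.zeros((N, h), dtype=self.dtype)
        # sequential part: only the recurrent propagation of dh/dc
        for t in range(T - 1, -1, -1):
            i = gates[t][:, :h]
            f = gates[t][:, h : 2 * h]
            g = gates[t][:, 2 * h : 3 * h]
            o = gates[t][:, 3 * h :]
            c_prev = C[t - 1] if t > 0 else 0.0
            tanh_c = np.tanh(C[t])

            dh = dH[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            dz = dZ[t]
            dz[:, :h] = dc * g * i * (1 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1 - g**2)
            dz[:, 3 * h :] = do * o * (1 - o)
            dh_next = dz @ self.U.T
            dc_next = dc * f
        # kernel gradients and dX as single large matmuls over all timesteps
        Xf = X.reshape(N * T, d)  # (N,T,d) flattened
        dZf = dZ.transpose(1, 0, 2).reshape(N * T, 4 * h)
        self.dW[:] = Xf.T @ dZf
        Hprev = np.concatenate([np.zeros((1, N, h), dtype=self.dtype), H[:-1]], axis=0)
        self.dU[:] = Hprev.reshape(T * N, h).T @ dZ.reshape(T * N, 4 * h)
        self.db[:] = dZf.sum(axis=0)
        dX = (dZf @ self.W.T).reshape(N, T, d)
        self._cache = None
        return dX


class DenseLayer:
    """Fully connected layer with ReLU or linear activation."""

    def __init__(self, input_dim: int, units: int, *, activation: str,
                 rng: np.random.Generator, dtype=np.float32):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.dtype = dtype
        self.W = _glorot_uniform(rng, input_dim, units, (input_dim, units)).astype(dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: dict | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, X: np.ndarray, *, cache: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        z = X @ self.W + self.b
        out = np.maximum(z, 0.0) if self.activation == "relu" else z
        if cache:
            self._cache = {"X": X, "z": z}
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cache = self._cache
        if cache is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        X, z = cache["X"], cache["z"]
        dout = np.asarray(dout, dtype=self.dtype)
        dz = dout * (z > 0) if self.activation == "relu" else dout
        self.dW[:] = X.T @ dz
        self.db[:] = dz.sum(axis=0)
        self._cache = None
        return dz @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    Returns (loss, probabilities, dlogits) with dlogits already divided by
    the batch size.
    """
    probs = softmax(logits)
    n = len(logits)
    logp = logits - logits.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    loss = float(-(onehot * logp).sum() / n)
    dlogits = (probs - onehot) / n
    return loss, probs, dlogits


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
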
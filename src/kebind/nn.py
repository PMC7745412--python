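"""NumPy neural-network building blocks with explicit backpropagation.

Layers used by the binding-site classifier: length-preserving ("same")
1-D convolution, masked ReLU, non-overlapping max-pooling, an LSTM
direction with per-example length masking, dense layers, dropout and an
Adam optimizer.  Every layer caches what its backward pass needs; batches
are ``(B, T, C)`` arrays right-padded with zeros plus a ``lengths`` vector
of true position counts, and padded positions never influence outputs or
gradients.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "sigmoid",
    "Conv1dSame",
    "MaskedReLU",
    "MaxPool1d",
    "GlobalMaxPool",
    "LSTMDirection",
    "BiLSTM",
    "Dense",
    "Dropout",
    "Adam",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp finite and, in float64, keeps sigma strictly inside (0,1)
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1dSame:
    """1-D convolution with zero 'same' padding: output length = input length.

    Output position t sees input positions [t - (K-1)//2, t + K//2].
    """

    def __init__(self, kernel: int, c_in: int, filters: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.kernel = kernel
        self.W = glorot_uniform(rng, (kernel, c_in, filters),
                                kernel * c_in, filters, dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self._cache = None

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, C = X.shape
        K = self.kernel
        left = (K - 1) // 2
        Xp = np.zeros((B, T + K - 1, C), dtype=X.dtype)
        Xp[:, left : left + T] = X
        out = np.zeros((B, T, self.W.shape[2]), dtype=X.dtype)
        for k in range(K):
            out += Xp[:, k : k + T] @ self.W[k]
        out += self.b
        self._cache = (Xp, T, left)
        return out

    def backward(self, dY: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        Xp, T, left = self._cache
        K = self.kernel
        B = dY.shape[0]
        F = dY.shape[2]
        dW = np.zeros_like(self.W)
        dXp = np.zeros_like(Xp)
        dY2 = dY.reshape(-1, F)
        for k in range(K):
            dW[k] = Xp[:, k : k + T].reshape(dY2.shape[0], -1).T @ dY2
            dXp[:, k : k + T] += dY @ self.W[k].T
        db = dY.sum(axis=(0, 1))
        dX = dXp[:, left : left + T]
        return dX, {"W": dW, "b": db}


class MaskedReLU:
    """ReLU that also zeroes all positions at or beyond each example's length."""

    def __init__(self) -> None:
        self._mask = None

    def forward(self, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        T = X.shape[1]
        valid = (np.arange(T)[None, :] < lengths[:, None])[:, :, None]
        self._mask = (X > 0) & valid
        return np.where(self._mask, X, 0.0).astype(X.dtype)

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dY, 0.0).astype(dY.dtype)


class MaxPool1d:
    """Non-overlapping max pool of width ``w``; output length floor(T / w).

    Per-example valid length becomes floor(length / w): only windows lying
    fully inside the valid region survive; the rest are zeroed.
    """

    def __init__(self, width: int = 2) -> None:
        self.width = width
        self._cache = None

    def forward(self, X: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, T, F = X.shape
        w = self.width
        T2 = T // w
        Xr = X[:, : T2 * w].reshape(B, T2, w, F)
        idx = Xr.argmax(axis=2)
        Y = np.take_along_axis(Xr, idx[:, :, None, :], axis=2).squeeze(2)
        new_lengths = lengths // w
        valid = (np.arange(T2)[None, :] < new_lengths[:, None])[:, :, None]
        Y = np.where(valid, Y, 0.0).astype(X.dtype)
        self._cache = (idx, (B, T, F), valid)
        return Y, new_lengths

    def backward(self, dY: np.ndarray) -> np.ndarray:
        idx, (B, T, F), valid = self._cache
        w = self.width
        T2 = T // w
        dY = np.where(valid, dY, 0.0).astype(dY.dtype)
        dXr = np.zeros((B, T2, w, F), dtype=dY.dtype)
        np.put_along_axis(dXr, idx[:, :, None, :], dY[:, :, None, :], axis=2)
        dX = np.zeros((B, T, F), dtype=dY.dtype)
        dX[:, : T2 * w] = dXr.reshape(B, T2 * w, F)
        return dX


class GlobalMaxPool:
    """Max over all valid positions -> (B, F)."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        B, T, F = X.shape
        valid = np.arange(T)[None, :] < lengths[:, None]
        Xm = np.where(valid[:, :, None], X, -np.inf)
        idx = Xm.argmax(axis=1)  # (B, F)
        Y = np.take_along_axis(X, idx[:, None, :], axis=1).squeeze(1)
        self._cache = (idx, X.shape)
        return Y

    def backward(self, dY: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        dX = np.zeros(shape, dtype=dY.dtype)
        np.put_along_axis(dX, idx[:, None, :], dY[:, None, :], axis=1)
        return dX


class LSTMDirection:
    """One LSTM scan direction with per-example length masking.

    Gate order in the packed matrices is (input, forget, candidate, output).
    The forget-gate bias starts at 1 to ease gradient flow early in
    training.  Only the final hidden state (at the last valid step of the
    scan) is returned; while a position is beyond an example's length the
    state simply carries over, so padding never enters the recurrence.
    """

    def __init__(self, c_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32, forget_bias: float = 1.0) -> None:
        self.units = units
        H = units
        self.W = glorot_uniform(rng, (c_in, 4 * H), c_in, 4 * H, dtype)
        self.U = glorot_uniform(rng, (H, 4 * H), H, 4 * H, dtype)
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H : 2 * H] = forget_bias
        self._cache = None

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.U": self.U, f"{prefix}.b": self.b}

    def forward(self, X: np.ndarray, lengths: np.ndarray,
                reverse: bool = False) -> np.ndarray:
        B, T, C = X.shape
        H = self.units
        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        order = range(T - 1, -1, -1) if reverse else range(T)
        steps = []
        for t in order:
            x = X[:, t]
            z = x @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            m = (lengths > t).astype(X.dtype)[:, None]
            steps.append((t, h, c, i, f, g, o, tanh_c, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        self._cache = (X.shape, X.dtype, steps, X)
        return h

    def backward(self, dh_final: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        shape, dtype, steps, X = self._cache
        B, T, C = shape
        H = self.units
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros(shape, dtype=dtype)
        dh = dh_final.astype(dtype)
        dc = np.zeros((B, H), dtype=dtype)
        for t, h_prev, c_prev, i, f, g, o, tanh_c, m in reversed(steps):
            dh_new = dh * m
            dh_carry = dh * (1.0 - m)
            dc_new = dc * m
            dc_carry = dc * (1.0 - m)
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1.0 - tanh_c**2)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dc = dc_new * f + dc_carry
            dz = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 dg * (1.0 - g**2), do * o * (1.0 - o)],
                axis=1,
            )
            x = X[:, t]
            dW += x.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh = dz @ self.U.T + dh_carry
        return dX, {"W": dW, "U": dU, "b": db}


class BiLSTM:
    """Bidirectional LSTM; final hidden states of both directions concatenated.

    With ``units`` per direction the output feature size is ``2 * units``.
    """

    def __init__(self, c_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.fw = LSTMDirection(c_in, units, rng, dtype)
        self.bw = LSTMDirection(c_in, units, rng, dtype)
        self.units = units

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {**self.fw.params(f"{prefix}.fw"), **self.bw.params(f"{prefix}.bw")}

    def forward(self, X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        h_fw = self.fw.forward(X, lengths, reverse=False)
        h_bw = self.bw.forward(X, lengths, reverse=True)
        return np.concatenate([h_fw, h_bw], axis=1)

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        H = self.units
        dX_fw, g_fw = self.fw.backward(dH[:, :H])
        dX_bw, g_bw = self.bw.backward(dH[:, H:])
        grads = {f"fw.{k}": v for k, v in g_fw.items()}
        grads.update({f"bw.{k}": v for k, v in g_bw.items()})
        return dX_fw + dX_bw, grads


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.W = glorot_uniform(rng, (c_in, c_out), c_in, c_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._cache = X
        return X @ self.W + self.b

    def backward(self, dY: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        X = self._cache
        return dY @ self.W.T, {"W": X.T @ dY, "b": dY.sum(axis=0)}


class Dropout:
    """Inverted dropout; identity when ``train=False`` or rate 0."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: Optional[np.ndarray] = None

    def forward(self, X: np.ndarray, train: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return X
        keep = 1.0 - self.rate
        self._mask = (rng.random(X.shape) < keep).astype(X.dtype) / keep
        return X * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dY
        return dY * self._mask


class Adam:
    """Adam optimizer over a named-parameter dictionary, with optional
    decoupled weight decay (applied to matrices, not biases)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in params.items():
            g = grads[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)
            if self.weight_decay and p.ndim > 1:
                p -= (self.lr * self.weight_decay) * p
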
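"""A compact numpy layer library with manual backpropagation.

Implements exactly what the window classifiers need: an embedding table, a
one-hot encoder, 1-D convolution (im2col + matmul, "same" zero padding),
max pooling, nearest-neighbour upsampling, dense layers, an LSTM with
padding masks, softmax cross-entropy (whole-window and per-position with a
position mask), and Adam. Forward passes cache what backward needs; every
layer's backward returns the input gradient and accumulates parameter
gradients. All floats are float32; all initialisation draws from an
explicit ``numpy.random.Generator`` so runs are bit-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    def parameters(self) -> list[Parameter]:
        return []


# ---------------------------------------------------------------------------
# encoders


class Embedding(Module):
    """Index -> dense vector lookup. Input (B, L) int, output (B, D, L)."""

    def __init__(self, n_indices: int, dim: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.1, size=(n_indices, dim)))

    def parameters(self):
        return [self.table]

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.table.value[idx].transpose(0, 2, 1)  # (B, D, L)

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.table.grad, self._idx, dy.transpose(0, 2, 1))


class OneHot(Module):
    """Index -> fixed one-hot channels. Input (B, L) int, output (B, V, L).

    The raw-index (no-embedding) encoder for the ablation variants; it has
    no trainable parameters and padding (index 0) maps to the zero vector.
    """

    def __init__(self, n_indices: int):
        self.n_indices = n_indices

    def forward(self, idx: np.ndarray) -> np.ndarray:
        B, L = idx.shape
        out = np.zeros((B, self.n_indices, L), dtype=DTYPE)
        b, l = np.nonzero(idx > 0)
        out[b, idx[b, l], l] = 1.0
        return out

    def backward(self, dy: np.ndarray) -> None:
        return None


# ---------------------------------------------------------------------------
# convolutional pieces


class Conv1d(Module):
    """1-D convolution, stride 1, zero-padded to preserve length.

    Input (B, Cin, L) -> output (B, Cout, L). For even kernels the extra
    padding goes on the left, matching the "zero padding strategy to
    maintain the original length" convention.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        scale = np.sqrt(2.0 / (cin * kernel))  # He init for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, kernel)))
        self.bias = Parameter(np.zeros(cout))
        self.kernel = kernel
        self.cin, self.cout = cin, cout

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        k = self.kernel
        pl = k // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C * k)
        Wm = self.weight.value.reshape(self.cout, C * k)
        y = cols2 @ Wm.T + self.bias.value
        self._cols2, self._shape, self._pads = cols2, (B, C, L), (pl, pr)
        return y.reshape(B, L, self.cout).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        k = self.kernel
        pl, pr = self._pads
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.cout)
        Wm = self.weight.value.reshape(self.cout, C * k)
        self.weight.grad += (dy2.T @ self._cols2).reshape(self.weight.value.shape)
        self.bias.grad += dy2.sum(axis=0)
        dcols = (dy2 @ Wm).reshape(B, L, C, k).transpose(0, 2, 1, 3)  # (B, C, L, k)
        dxp = np.zeros((B, C, L + pl + pr), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j]
        return dxp[:, :, pl:pl + L]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool1d(Module):
    """Non-overlapping max pooling; input length must divide the pool size."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        if L % self.pool:
            raise ValueError(f"input length {L} not divisible by pool {self.pool}")
        xr = x.reshape(B, C, L // self.pool, self.pool)
        self._argmax = xr.argmax(axis=3)
        self._shape = (B, C, L)
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        dxr = np.zeros((B, C, L // self.pool, self.pool), dtype=DTYPE)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        return dxr.reshape(B, C, L)


class Upsample1d(Module):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L2 = dy.shape
        return dy.reshape(B, C, L2 // self.factor, self.factor).sum(axis=3)


class GlobalAvgPool(Module):
    """(B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


# ---------------------------------------------------------------------------
# recurrence


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Module):
    """Single-layer LSTM returning the final hidden state.

    Input (B, L, D) with a float mask (B, L): masked (padding) steps leave
    the hidden and cell state untouched, so left-padded windows — including
    a fully padded one — produce a well-defined forward pass. The forget
    gate bias starts at 1, the usual stabilisation.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / max(dim, hidden))
        self.Wx = Parameter(rng.normal(0.0, scale, size=(dim, 4 * hidden)))
        self.Wh = Parameter(rng.normal(0.0, scale, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Parameter(b)
        self.hidden = hidden

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, L, D = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        self._cache = []
        self._x, self._mask = x, mask.astype(DTYPE)
        for t in range(L):
            m = self._mask[:, t:t + 1]
            a = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        B, L, D = self._x.shape
        H = self.hidden
        dx = np.zeros_like(self._x)
        dc = np.zeros((B, H), dtype=DTYPE)
        dh = dh.copy()
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc, m = self._cache[t]
            dhn = dh * m
            dcn = dc * m
            do = dhn * tc
            dcn = dcn + dhn * o * (1.0 - tc * tc)
            di = dcn * g
            df = dcn * c_prev
            dg = dcn * i
            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g * g), do * o * (1.0 - o)],
                axis=1,
            )
            self.Wx.grad += self._x[:, t, :].T @ da
            self.Wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t, :] = da @ self.Wx.value.T
            dh = da @ self.Wh.value.T + dh * (1.0 - m)
            dc = dcn * f + dc * (1.0 - m)
        return dx


# ---------------------------------------------------------------------------
# losses


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over windows. logits (B, K), y (B,) int."""
    B = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
    dlogits = p
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), (dlogits / B).astype(DTYPE)


def cross_entropy_per_position(
    logits: np.ndarray, y: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over masked positions.

    logits (B, K, L); y (B, L) int; mask (B, L) with 1 at real events and
    0 at padding — padded positions contribute nothing to loss or grad.
    """
    p = softmax(logits, axis=1)
    B, K, L = logits.shape
    m = mask.astype(DTYPE)
    n = max(m.sum(), 1.0)
    picked = np.take_along_axis(p, y[:, None, :], axis=1)[:, 0, :]
    loss = -(np.log(np.clip(picked, 1e-12, None)) * m).sum() / n
    dlogits = p
    bi, li = np.meshgrid(np.arange(B), np.arange(L), indexing="ij")
    dlogits[bi, y, li] -= 1.0
    dlogits *= (m / n)[:, None, :]
    return float(loss), dlogits.astype(DTYPE)


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
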
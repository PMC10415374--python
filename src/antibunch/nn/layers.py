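"""Minimal neural-network layers on numpy.

Only what the histogram regression model needs: same-padding 1-D
convolution (computed as an im2col GEMM so BLAS does the heavy
lifting), ReLU, max-pooling, inverted dropout and dense layers, plus
the Adamax optimizer and the mean-absolute-percentage-error loss.
Everything is deterministic given the generators passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1DSame",
    "Dense",
    "relu",
    "relu_backward",
    "MaxPool1D",
    "Dropout",
    "Adamax",
    "mape_loss",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1DSame:
    """1-D convolution with stride 1 and 'same' zero padding.

    Weights have shape (kernel, c_in, c_out).  For an even kernel the
    padding splits as (k-1)//2 on the left and the remainder on the
    right (Keras convention).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.dtype = dtype
        fan_in = kernel * c_in
        self.W = glorot_uniform(rng, (kernel, c_in, c_out), fan_in, c_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._col: np.ndarray | None = None
        self._in_len = 0

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (B, L, c_in) -> (B, L, c_out)
        B, L, _ = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # im2col by copying shifted contiguous slabs into one buffer, so
        # BLAS sees a single big GEMM per layer
        buf = np.empty((B, L, self.k, self.c_in), dtype=x.dtype)
        for k in range(self.k):
            np.copyto(buf[:, :, k, :], xp[:, k : k + L, :])
        col = buf.reshape(B * L, self.k * self.c_in)
        out = col @ self._w2d()
        out += self.b
        if train:
            self._col = col
            self._in_len = L
        return out.reshape(B, L, self.c_out)

    def _w2d(self) -> np.ndarray:
        # (k, c_in, c_out) -> (k*c_in, c_out) with tap-major ordering,
        # matching the concatenated im2col layout
        return self.W.reshape(self.k * self.c_in, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        B, L, _ = dy.shape
        dyf = np.ascontiguousarray(dy).reshape(B * L, self.c_out)
        col = self._col
        self.dW = (col.T @ dyf).reshape(self.k, self.c_in, self.c_out)
        self.db = dyf.sum(axis=0)
        self._col = None
        if not need_dx:
            return None
        # dcol laid out tap-major like the forward im2col
        dcol = (dyf @ self._w2d().T).reshape(B, L, self.k, self.c_in)
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        dxp = np.zeros((B, L + pl + pr, self.c_in), dtype=dy.dtype)
        for k in range(self.k):
            dxp[:, k : k + L, :] += dcol[:, :, k, :]
        return dxp[:, pl : pl + L, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        if not need_dx:
            return None
        return dy @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dy: np.ndarray, activated: np.ndarray) -> np.ndarray:
    # in place: dy is layer-owned scratch by the time this runs
    dy *= activated > 0
    return dy


class MaxPool1D:
    """Non-overlapping max pooling along the length axis (trailing
    elements that do not fill a window are dropped)."""

    def __init__(self, size: int = 2):
        self.size = size
        self._arg: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.size
        xr = x[:, : Lo * self.size, :].reshape(B, Lo, self.size, C)
        if train:
            self._arg = xr.argmax(axis=2)
            self._in_len = L
            return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        B, Lo, C = dy.shape
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        dxr = dx[:, : Lo * self.size, :].reshape(B, Lo, self.size, C)
        bi, li, ci = np.ogrid[:B, :Lo, :C]
        dxr[bi, li, self._arg, ci] = dy
        return dx


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        self._mask = (u < keep).astype(x.dtype)
        self._mask /= keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Adamax:
    """Adamax: Adam with an infinity-norm second moment (Kingma & Ba)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.002, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bias = 1.0 - self.b1**self.t
        for p, g, m, u in zip(self.params, grads, self.m, self.u):
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p -= (self.lr / bias) * m / (u + self.eps)


def mape_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute percentage error and its gradient w.r.t. ``pred``.

    Targets must be strictly positive (labels are clamped upstream).
    """
    if np.any(target <= 0):
        raise ValueError("MAPE requires strictly positive targets")
    n = pred.shape[0]
    diff = pred - target
    loss = 100.0 * float(np.mean(np.abs(diff) / target))
    grad = (100.0 / n) * np.sign(diff) / target
    return loss, grad.astype(pred.dtype)
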
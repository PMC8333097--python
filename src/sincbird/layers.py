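"""Minimal NumPy neural-network layers with explicit backpropagation.

Everything the frame classifier needs — 1-d convolutions (including the
sinc-parameterized variant whose kernel is an analytic function of two
cutoff parameters per filter), max pooling, layer/batch normalization,
leaky ReLU, dropout, linear layers, LogSoftmax and RMSprop — implemented
on plain ndarrays.  Each layer caches what its backward pass needs during
``forward`` and accumulates parameter gradients in ``self.grads``.

Array layout: convolutional tensors are (batch, channels, length); fully
connected tensors are (batch, features).
"""

from __future__ import annotations

import numpy as np

from .sinc import hamming_window

__all__ = [
    "Layer", "Conv1d", "SincConv1d", "MaxPool1d", "LayerNorm", "BatchNorm1d",
    "LeakyReLU", "Dropout", "Linear", "Flatten", "LogSoftmax", "Sequential",
    "RMSprop", "nll_loss",
]


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


# ---------------------------------------------------------------------------
# convolution machinery shared by the standard and sinc first layers
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Valid cross-correlation of (B,C,L) with (O,C,K) -> (B,O,L-K+1)."""
    k = w.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # B,C,Lo,K
    y = np.tensordot(win, w, axes=([1, 3], [1, 2]))  # B,Lo,O
    return np.ascontiguousarray(np.moveaxis(y, 1, 2)), win


def _conv_backward(win: np.ndarray, w: np.ndarray,
                   dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the valid cross-correlation.

    ``win`` is the cached sliding-window view of the forward input and
    ``dy`` the upstream gradient (B,O,Lo).  The input gradient is a full
    correlation, computed as one (B*Lo, O) x (O, C*K) matrix product
    followed by K shifted accumulations — far cheaper than materializing
    the padded sliding-window tensor.
    """
    k = w.shape[2]
    b, o, lo = dy.shape
    c = w.shape[1]
    dw = np.tensordot(dy, win, axes=([0, 2], [0, 2]))  # O,C,K
    g = np.tensordot(dy, w, axes=([1], [0]))           # B,Lo,C,K
    dx = np.zeros((b, c, lo + k - 1))
    for j in range(k):
        dx[:, :, j:j + lo] += np.moveaxis(g[:, :, :, j], 1, 2)
    return dw, dx


class Conv1d(Layer):
    """Standard valid 1-d convolution (cross-correlation convention)."""

    def __init__(self, c_in: int, c_out: int, kernel_len: int,
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        self.kernel_len = kernel_len
        fan_in = c_in * kernel_len
        self.params["W"] = _uniform_init(rng, (c_out, c_in, kernel_len), fan_in)
        self.use_bias = bias
        if bias:
            self.params["b"] = _uniform_init(rng, (c_out,), fan_in)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, self._win = _conv_forward(x, self.params["W"])
        if self.use_bias:
            y += self.params["b"][None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"], dx = _conv_backward(self._win, self.params["W"], dy)
        if self.use_bias:
            self.grads["b"] = dy.sum(axis=(0, 2))
        self._win = None
        return dx


class SincConv1d(Layer):
    """Band-pass sinc convolution with two learnable parameters per filter.

    The materialized kernel for filter j is

        k_j[n] = (2 fh_j sinc(2 pi fh_j n) - 2 fl_j sinc(2 pi fl_j n)) w[n]

    with normalized cutoffs fh = f_h/fs, fl = f_l/fs derived from raw
    parameters via |p_low| and |p_low| + |p_band| clipped to Nyquist, and w
    a Hamming window.  The backward pass uses the closed-form derivative
    d k / d fh = 2 cos(2 pi fh n) w[n] (and its negative for fl), chained
    through the constraint mapping with subgradient 0 where clipped.
    """

    def __init__(self, n_filt: int, kernel_len: int, fs: float,
                 p_low: np.ndarray, p_band: np.ndarray) -> None:
        super().__init__()
        if kernel_len % 2 == 0:
            raise ValueError("kernel_len must be odd")
        self.n_filt = n_filt
        self.kernel_len = kernel_len
        self.fs = float(fs)
        self.params["p_low"] = np.asarray(p_low, dtype=float).copy()
        self.params["p_band"] = np.asarray(p_band, dtype=float).copy()
        half = (kernel_len - 1) // 2
        self._n = np.arange(-half, half + 1, dtype=float)
        self._window = hamming_window(kernel_len)

    def _materialize(self) -> tuple[np.ndarray, dict]:
        fs = self.fs
        a = np.abs(self.params["p_low"])
        f_l = np.minimum(a, fs / 2)
        b = f_l + np.abs(self.params["p_band"])
        f_h = np.minimum(b, fs / 2)
        fl = (f_l / fs)[:, None]
        fh = (f_h / fs)[:, None]
        n = self._n[None, :]
        arg_h = 2 * np.pi * fh * n
        arg_l = 2 * np.pi * fl * n
        g = 2 * fh * np.sinc(arg_h / np.pi) - 2 * fl * np.sinc(arg_l / np.pi)
        kernels = g * self._window[None, :]
        cache = {
            "arg_h": arg_h, "arg_l": arg_l,
            "mask_l": (a <= fs / 2).astype(float),
            "mask_h": (b <= fs / 2).astype(float),
            "sign_low": np.sign(self.params["p_low"]),
            "sign_band": np.sign(self.params["p_band"]),
        }
        return kernels, cache

    def kernels(self) -> np.ndarray:
        return self._materialize()[0]

    def cutoffs(self) -> tuple[np.ndarray, np.ndarray]:
        from .sinc import effective_cutoffs
        return effective_cutoffs(self.params["p_low"], self.params["p_band"], self.fs)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != 1:
            raise ValueError("sinc frontend expects a single input channel")
        kernels, self._cache = self._materialize()
        w = kernels[:, None, :]  # (n_filt, 1, K)
        y, self._win = _conv_forward(x, w)
        self._w = w
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dw, dx = _conv_backward(self._win, self._w, dy)
        dk = dw[:, 0, :]  # (n_filt, K)
        c = self._cache
        w = self._window[None, :]
        # gradients w.r.t. normalized cutoffs, then to Hz, then to raw params
        g_fh = np.sum(dk * 2.0 * np.cos(c["arg_h"]) * w, axis=1) / self.fs
        g_fl = np.sum(dk * (-2.0) * np.cos(c["arg_l"]) * w, axis=1) / self.fs
        g_fh = g_fh * c["mask_h"]
        self.grads["p_band"] = g_fh * c["sign_band"]
        self.grads["p_low"] = (g_fl + g_fh) * c["mask_l"] * c["sign_low"]
        self._win = self._w = self._cache = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the length axis; remainder dropped."""

    def __init__(self, pool_len: int) -> None:
        super().__init__()
        self.pool_len = pool_len

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.pool_len
        b, c, length = x.shape
        lo = length // p
        xt = x[:, :, : lo * p].reshape(b, c, lo, p)
        self._idx = xt.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.pool_len
        b, c, lo = dy.shape
        dxt = np.zeros((b, c, lo, p))
        np.put_along_axis(dxt, self._idx[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : lo * p] = dxt.reshape(b, c, lo * p)
        return dx


class LayerNorm(Layer):
    """Per-sample normalization over all non-batch axes, with affine params."""

    def __init__(self, shape: tuple[int, ...], eps: float = 1e-5) -> None:
        super().__init__()
        self.shape = tuple(shape)
        self.eps = eps
        self.params["gamma"] = np.ones(self.shape)
        self.params["beta"] = np.zeros(self.shape)
        self._axes = tuple(range(1, 1 + len(self.shape)))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mu = x.mean(axis=self._axes, keepdims=True)
        var = x.var(axis=self._axes, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes_batch = (0,)
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes_batch)
        self.grads["beta"] = dy.sum(axis=axes_batch)
        dxhat = dy * self.params["gamma"]
        m1 = dxhat.mean(axis=self._axes, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=self._axes, keepdims=True)
        dx = self._inv * (dxhat - m1 - self._xhat * m2)
        self._inv = self._xhat = None
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over (batch, features) with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["gamma"] = (dy * self._xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if self._training:
            m1 = dxhat.mean(axis=0)
            m2 = (dxhat * self._xhat).mean(axis=0)
            dx = self._inv * (dxhat - m1 - self._xhat * m2)
        else:
            dx = self._inv * dxhat
        self._inv = self._xhat = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at rate 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _uniform_init(rng, (n_in, n_out), n_in)
        self.params["b"] = _uniform_init(rng, (n_out,), n_in)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class LogSoftmax(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        self._p = np.exp(logp)
        return logp

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy - self._p * dy.sum(axis=1, keepdims=True)
        self._p = None
        return dx


class Sequential:
    """Ordered layer stack with a shared train/eval switch."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


def nll_loss(logp: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. log-probabilities."""
    b = logp.shape[0]
    idx = np.arange(b)
    loss = -float(logp[idx, targets].mean())
    dlogp = np.zeros_like(logp)
    dlogp[idx, targets] = -1.0 / b
    return loss, dlogp


class RMSprop:
    """RMSprop with smoothing constant alpha, no momentum, no weight decay."""

    def __init__(self, model: Sequential, lr: float = 0.001,
                 alpha: float = 0.95, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._ms: list[dict[str, np.ndarray]] = [
            {name: np.zeros_like(p) for name, p in layer.params.items()}
            for layer in model.layers
        ]

    def step(self) -> None:
        for layer, ms in zip(self.model.layers, self._ms):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                ms[name] = self.alpha * ms[name] + (1 - self.alpha) * g * g
                p -= self.lr * g / (np.sqrt(ms[name]) + self.eps)
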
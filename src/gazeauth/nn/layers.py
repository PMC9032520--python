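"""Layers with explicit forward/backward passes.

Convolutions use stride 1 with 'same' zero padding and are evaluated via
im2col + BLAS matmul; the col2im in the backward pass reduces to k shifted
additions because the stride is 1.  All layers cache what backward needs on
forward and write parameter gradients into pre-allocated ``.grads`` arrays.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameter-free unless overridden."""

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs; grads are overwritten each backward pass."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Layer):
    """Dilated 1-D convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin, cout, kernel, dilation=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.d = cin, cout, kernel, dilation
        self.W = _he_init(rng, (cout, cin * kernel), cin * kernel, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        total = (kernel - 1) * dilation
        self.pad_l = total // 2
        self.pad_r = total - self.pad_l

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        B, C, L = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        cols = np.empty((B, C, self.k, L), dtype=x.dtype)
        for j in range(self.k):
            cols[:, :, j, :] = xpad[:, :, j * self.d : j * self.d + L]
        self._cols = cols.reshape(B, C * self.k, L)
        self._L = L
        return np.matmul(self.W, self._cols) + self.b[:, None]

    def backward(self, dy):
        B, _, L = dy.shape
        self.dW[...] = np.tensordot(dy, self._cols, axes=([0, 2], [0, 2]))
        self.db[...] = dy.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dy).reshape(B, self.cin, self.k, L)
        Lp = L + self.pad_l + self.pad_r
        dxpad = np.zeros((B, self.cin, Lp), dtype=dy.dtype)
        for j in range(self.k):
            dxpad[:, :, j * self.d : j * self.d + L] += dcols[:, :, j, :]
        return dxpad[:, :, self.pad_l : self.pad_l + L]

    def state(self):
        return {"W": self.W, "b": self.b}

    def load_state(self, s):
        self.W[...] = s["W"]
        self.b[...] = s["b"]


class Conv2d(Layer):
    """2-D convolution, stride 1, square kernel, 'same' zero padding."""

    def __init__(self, cin, cout, kernel, dilation=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.d = cin, cout, kernel, dilation
        fan_in = cin * kernel * kernel
        self.W = _he_init(rng, (cout, fan_in), fan_in, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        total = (kernel - 1) * dilation
        self.pad_l = total // 2
        self.pad_r = total - self.pad_l

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        B, C, H, W_ = x.shape
        pl, pr = self.pad_l, self.pad_r
        xpad = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        cols = np.empty((B, C, self.k, self.k, H, W_), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, i, j] = xpad[
                    :, :, i * self.d : i * self.d + H, j * self.d : j * self.d + W_
                ]
        self._cols = cols.reshape(B, C * self.k * self.k, H * W_)
        self._hw = (H, W_)
        y = np.matmul(self.W, self._cols) + self.b[:, None]
        return y.reshape(B, self.cout, H, W_)

    def backward(self, dy):
        B = dy.shape[0]
        H, W_ = self._hw
        dyf = dy.reshape(B, self.cout, H * W_)
        self.dW[...] = np.tensordot(dyf, self._cols, axes=([0, 2], [0, 2]))
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dyf).reshape(B, self.cin, self.k, self.k, H, W_)
        pl, pr = self.pad_l, self.pad_r
        dxpad = np.zeros((B, self.cin, H + pl + pr, W_ + pl + pr), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxpad[
                    :, :, i * self.d : i * self.d + H, j * self.d : j * self.d + W_
                ] += dcols[:, :, i, j]
        return dxpad[:, :, pl : pl + H, pl : pl + W_]

    def state(self):
        return {"W": self.W, "b": self.b}

    def load_state(self, s):
        self.W[...] = s["W"]
        self.b[...] = s["b"]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(x.dtype)
        self._xhat = (x - mu.reshape(sh).astype(x.dtype)) / self._std.reshape(sh)
        self._axes = axes
        self._train = train
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, dy):
        sh = self._shape(dy)
        axes = self._axes
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(sh)
        if not self._train:
            # running statistics are constants in evaluation mode
            return dxhat / self._std.reshape(sh)
        mean_dxhat = dxhat.mean(axis=axes).reshape(sh)
        mean_dxhat_xhat = (dxhat * self._xhat).mean(axis=axes).reshape(sh)
        return (dxhat - mean_dxhat - self._xhat * mean_dxhat_xhat) / self._std.reshape(sh)

    def state(self):
        return {
            "gamma": self.gamma, "beta": self.beta,
            "running_mean": self.running_mean, "running_var": self.running_var,
        }

    def load_state(self, s):
        self.gamma[...] = s["gamma"]
        self.beta[...] = s["beta"]
        self.running_mean[...] = s["running_mean"]
        self.running_var[...] = s["running_var"]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, kernel=4):
        self.k = kernel

    def forward(self, x, train=True):
        B, C, L = x.shape
        Lo = L // self.k
        xr = x[:, :, : Lo * self.k].reshape(B, C, Lo, self.k)
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, Lo = dy.shape
        dxr = np.zeros((B, C, Lo, self.k), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._inshape, dtype=dy.dtype)
        dx[:, :, : Lo * self.k] = dxr.reshape(B, C, Lo * self.k)
        return dx


class MaxPool2d(Layer):
    """Non-overlapping 2-D max pooling (square window)."""

    def __init__(self, kernel=2):
        self.k = kernel

    def forward(self, x, train=True):
        B, C, H, W_ = x.shape
        k = self.k
        Ho, Wo = H // k, W_ // k
        xr = (
            x[:, :, : Ho * k, : Wo * k]
            .reshape(B, C, Ho, k, Wo, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Ho, Wo, k * k)
        )
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, Ho, Wo = dy.shape
        k = self.k
        dxr = np.zeros((B, C, Ho, Wo, k * k), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._inshape, dtype=dy.dtype)
        dx[:, :, : Ho * k, : Wo * k] = (
            dxr.reshape(B, C, Ho, Wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Ho * k, Wo * k)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, nin, nout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.W = _he_init(rng, (nout, nin), nin, dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W

    def state(self):
        return {"W": self.W, "b": self.b}

    def load_state(self, s):
        self.W[...] = s["W"]
        self.b[...] = s["b"]


class L2Norm(Layer):
    """Row-wise L2 normalization onto the unit hypersphere."""

    def __init__(self, eps=1e-12):
        self.eps = eps

    def forward(self, x, train=True):
        self._n = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        self._y = x / self._n
        return self._y

    def backward(self, dy):
        proj = (dy * self._y).sum(axis=1, keepdims=True)
        return (dy - self._y * proj) / self._n


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def state(self):
        return {
            str(i): lay.state() for i, lay in enumerate(self.layers) if lay.state()
        }

    def load_state(self, s):
        for i, lay in enumerate(self.layers):
            if str(i) in s:
                lay.load_state(s[str(i)])
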
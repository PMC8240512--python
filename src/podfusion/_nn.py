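"""Minimal NumPy neural-network core used by the detector and fusion models.

Layers operate on float64 arrays in NCHW layout (vectors are NxD). Each layer
implements ``forward`` and ``backward``; ``backward`` receives the gradient of
the loss w.r.t. the layer output and returns the gradient w.r.t. its input,
accumulating parameter gradients in ``.grads``. All layers are deterministic
given the RNG handed to ``init``; there is no hidden entropy.

The scale target is desk-scale training on one CPU: convolutions go through
im2col + GEMM, and pooling uses reshape tricks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameterless, stateless passthrough by default."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return getattr(self, "_grads", {})

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g.fill(0.0)

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for stride-1 'same' conv."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w, _, _ = win.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Scatter-add the inverse of ``_im2col``."""
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 'same' convolution via im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng=None, bias: bool = True):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        # He-normal fan-in init
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch * k * k))
        self.b = np.zeros(out_ch) if bias else None
        self._grads = {"W": np.zeros_like(self.W)}
        if bias:
            self._grads["b"] = np.zeros_like(self.b)
        self.training = True

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        out = self._cols @ self.W.T
        if self.b is not None:
            out += self.b
        n, _, h, w = x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, co, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, co)
        self._grads["W"] += g.T @ self._cols
        if self.b is not None:
            self._grads["b"] += g.sum(axis=0)
        gcols = g @ self.W
        return _col2im(gcols, self._x_shape, self.k, self.pad)


class BatchNorm2d(Layer):
    """Batch norm over (N,H,W) with running statistics for eval mode."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps
        self._grads = {"gamma": np.zeros(ch), "beta": np.zeros(ch)}
        self.training = True

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._var = var
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat = self._xhat
        self._grads["gamma"] += (grad * xhat).sum(axis=(0, 2, 3))
        self._grads["beta"] += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not self.training:
            return g / np.sqrt(self._var + self.eps)[None, :, None, None]
        inv = 1.0 / np.sqrt(self._var + self.eps)[None, :, None, None]
        gm = g.mean(axis=(0, 2, 3))
        gxh = (g * xhat).mean(axis=(0, 2, 3))
        return inv * (g - gm[None, :, None, None] - xhat * gxh[None, :, None, None])


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pool (floor on odd sizes); ties share the gradient."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"feature map {h}x{w} too small to pool")
        xc = x[:, :, : 2 * h2, : 2 * w2]
        xr = xc.reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._cnt = self._mask.sum(axis=(3, 5))
        return out

    def backward(self, grad):
        g = (grad / self._cnt)[:, :, :, None, :, None] * self._mask
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        out = np.zeros(self._in_shape)
        out[:, :, : 2 * h2, : 2 * w2] = g.reshape(n, c, 2 * h2, 2 * w2)
        return out


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self._grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self.training = True

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self._grads["W"] += grad.T @ self._x
        self._grads["b"] += grad.sum(axis=0)
        return grad @ self.W


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)
        self.training = True

    def train(self):
        self.training = True
        for l in self.layers:
            l.train()

    def eval(self):
        self.training = False
        for l in self.layers:
            l.eval()

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.params().items():
                out[f"{i}.{k}"] = v
            if isinstance(l, BatchNorm2d):
                for k, v in l.state().items():
                    out[f"{i}.{k}"] = v
        return out

    def load_params(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.layers):
            for k in l.params():
                l.params()[k][...] = state[f"{i}.{k}"]
            if isinstance(l, BatchNorm2d):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]


class Adam:
    """Adam over a collection of (param, grad) pairs from one or more nets."""

    def __init__(self, modules, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.pairs = []
        for mod in modules:
            layers = mod.layers if isinstance(mod, Sequential) else [mod]
            for l in layers:
                if isinstance(l, Sequential):
                    self.pairs.extend(
                        (p, sl.grads[k])
                        for sl in l.layers
                        for k, p in sl.params().items()
                    )
                else:
                    self.pairs.extend((p, l.grads[k]) for k, p in l.params().items())
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            if self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay  # decoupled decay
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g.fill(0.0)
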
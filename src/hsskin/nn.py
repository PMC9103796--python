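"""Minimal seeded convolutional-network engine on numpy.

Implements exactly the pieces the two-branch pixel classifier needs:
valid-mode 2-D/3-D convolutions (im2col via stride-tricks sliding windows
and BLAS tensordot), non-overlapping max-pooling, LeakyReLU, dense layers,
softmax cross-entropy, and Adam with the standard default parameters
(lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8).  Everything runs in float32;
initialization, shuffling and hence training are fully determined by a
single integer seed.

The engine favors clarity and exact reproducibility over speed; it is
sized for the desk-scale experiments this package runs, not for GPU-scale
training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "MaxPool",
    "LeakyReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "TwoBranchNet",
    "Adam",
    "softmax",
]


class Layer:
    """Base layer: parameters in .params / gradients in .grads (same keys)."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv(Layer):
    """Valid-mode convolution with ``ndim`` spatial dimensions (stride 1).

    Input (B, *spatial, Cin); kernel (*k, Cin, Cout).  He-normal init.
    Forward/backward run as im2col matmuls; in training mode the column
    matrix is cached and reused for the weight gradient.  A layer marked
    ``first`` (nothing trainable below it) skips the input gradient.
    """

    def __init__(self, ndim: int, in_channels: int, filters: int, kernel, rng,
                 name="", first=False, stride=None):
        super().__init__()
        self.ndim = int(ndim)
        self.kernel = tuple(int(k) for k in kernel)
        if len(self.kernel) != self.ndim:
            raise ValueError(f"kernel {kernel} must have {ndim} entries")
        self.stride = tuple(int(s) for s in stride) if stride else (1,) * self.ndim
        self.name = name
        self.first = bool(first)
        if any(s > 1 for s in self.stride) and not self.first:
            raise ValueError(
                f"conv block {name or '?'}: strided convolution is only supported "
                "as the first layer of a branch"
            )
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(
            0.0, scale, size=self.kernel + (in_channels, filters)
        ).astype(np.float32)
        self.params["b"] = np.zeros(filters, dtype=np.float32)
        self._cols = None
        self._out_sp = None

    def out_shape(self, in_shape):
        spatial = tuple(
            (d - k) // s + 1
            for d, k, s in zip(in_shape[: self.ndim], self.kernel, self.stride)
        )
        if any(sp < 1 for sp in spatial) or any(
            d < k for d, k in zip(in_shape[: self.ndim], self.kernel)
        ):
            raise ValueError(
                f"conv block {self.name or '?'}: kernel {self.kernel} does not fit "
                f"input {in_shape[: self.ndim]}"
            )
        return spatial + (self.params["W"].shape[-1],)

    def _w_matrix(self):
        # (*k, Cin, Cout) -> (Cin * prod(k), Cout), matching column layout
        w = np.moveaxis(self.params["W"], self.ndim, 0)
        return w.reshape(-1, w.shape[-1])

    def forward(self, x, train=False):
        nd = self.ndim
        # windows: (B, *out_sp, Cin, *k) -> columns (B * prod(out_sp), Cin * prod(k))
        v = sliding_window_view(x, self.kernel, axis=tuple(range(1, 1 + nd)))
        v = v[(slice(None),) + tuple(slice(None, None, s) for s in self.stride)]
        out_sp = v.shape[1 : 1 + nd]
        cols = np.ascontiguousarray(v, dtype=np.float32).reshape(
            x.shape[0] * int(np.prod(out_sp)), -1
        )
        if train:
            self._cols, self._out_sp, self._in_shape = cols, out_sp, x.shape
        y = cols @ self._w_matrix() + self.params["b"]
        return y.reshape((x.shape[0],) + out_sp + (-1,))

    def backward(self, dy):
        nd = self.ndim
        cout = dy.shape[-1]
        dyr = dy.reshape(-1, cout)
        dw = self._cols.T @ dyr  # (Cin * prod(k), Cout)
        dw = dw.reshape((self.params["W"].shape[nd],) + self.kernel + (cout,))
        self.grads["W"] = np.moveaxis(dw, 0, nd).astype(np.float32, copy=False)
        self.grads["b"] = dyr.sum(axis=0).astype(np.float32, copy=False)
        self._cols = None
        if self.first:
            return None  # nothing below needs a gradient
        # dX: full correlation of dy with the spatially flipped kernel
        pad = [(0, 0)] + [(k - 1, k - 1) for k in self.kernel] + [(0, 0)]
        dyp = np.pad(dy, pad)
        wf = self.params["W"][tuple(slice(None, None, -1) for _ in range(nd))]
        v2 = sliding_window_view(dyp, self.kernel, axis=tuple(range(1, 1 + nd)))
        win_axes = list(range(2 + nd, 2 + 2 * nd)) + [1 + nd]
        w_axes = list(range(nd)) + [nd + 1]  # contract Cout
        dx = np.tensordot(v2, wf, axes=(win_axes, w_axes))
        return dx.astype(np.float32, copy=False)


class MaxPool(Layer):
    """Non-overlapping max pooling; trailing rows/cols beyond a full block
    are cropped (their gradient is zero)."""

    def __init__(self, pool, name=""):
        super().__init__()
        self.pool = tuple(int(p) for p in pool)
        self.name = name
        self._cache = None

    def out_shape(self, in_shape):
        spatial = tuple(d // p for d, p in zip(in_shape[:-1], self.pool))
        if any(s < 1 for s in spatial):
            raise ValueError(
                f"pool block {self.name or '?'}: pool {self.pool} collapses input "
                f"{in_shape[:-1]} below 1"
            )
        return spatial + (in_shape[-1],)

    def forward(self, x, train=False):
        nd = len(self.pool)
        out_sp = [x.shape[1 + i] // self.pool[i] for i in range(nd)]
        crop = tuple(
            slice(0, out_sp[i] * self.pool[i]) for i in range(nd)
        )
        xc = x[(slice(None),) + crop]
        shape = [x.shape[0]]
        for o, p in zip(out_sp, self.pool):
            shape += [o, p]
        shape.append(x.shape[-1])
        xr = xc.reshape(shape)
        # move the pool axes (2, 4, ...) to the end and flatten them
        pool_axes = [2 + 2 * i for i in range(nd)]
        keep_axes = [0] + [1 + 2 * i for i in range(nd)] + [len(shape) - 1]
        xt = np.transpose(xr, keep_axes + pool_axes)
        blocks = xt.reshape(xt.shape[: 2 + nd] + (-1,))
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, out_sp, idx, keep_axes + pool_axes, xt.shape)
        return y

    def backward(self, dy):
        in_shape, out_sp, idx, perm, t_shape = self._cache
        nd = len(self.pool)
        blocks = np.zeros(idx.shape + (int(np.prod(self.pool)),), dtype=dy.dtype)
        np.put_along_axis(blocks, idx[..., None], dy[..., None], axis=-1)
        xt = blocks.reshape(t_shape)
        inv = np.argsort(perm)
        xr = np.transpose(xt, inv)
        dx = np.zeros(in_shape, dtype=dy.dtype)
        crop = tuple(slice(0, o * p) for o, p in zip(out_sp, self.pool))
        dx[(slice(None),) + crop] = xr.reshape(
            (in_shape[0],) + tuple(o * p for o, p in zip(out_sp, self.pool)) + (in_shape[-1],)
        )
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = float(slope)
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, scale, size=(in_features, units)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(units, dtype=np.float32)
        self._x = None

    def out_shape(self, in_shape):
        return (self.params["W"].shape[1],)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = (self._x.T @ dy).astype(np.float32, copy=False)
        self.grads["b"] = dy.sum(axis=0).astype(np.float32, copy=False)
        return dy @ self.params["W"].T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            for key in layer.params:
                yield layer, key


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TwoBranchNet:
    """Two feature branches whose flattened outputs feed shared dense layers.

    ``forward`` takes a pair (x3d, x2d): the spectral window as a 3-D
    volume (B, H, W, bands, 1) and the depth window (B, H, W, 1).
    """

    def __init__(self, branch3d: Sequential, branch2d: Sequential, head: Sequential,
                 n3d_features: int, n2d_features: int):
        self.branch3d = branch3d
        self.branch2d = branch2d
        self.head = head
        self._split = n3d_features
        self.n_features = n3d_features + n2d_features

    def forward(self, inputs, train: bool = False) -> np.ndarray:
        x3d, x2d = inputs
        f3 = self.branch3d.forward(x3d, train=train)
        f2 = self.branch2d.forward(x2d, train=train)
        return self.head.forward(np.concatenate([f3, f2], axis=1), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        self.branch3d.backward(dfeat[:, : self._split])
        self.branch2d.backward(dfeat[:, self._split :])

    def parameters(self):
        yield from self.branch3d.parameters()
        yield from self.branch2d.parameters()
        yield from self.head.parameters()

    def state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters (for checkpoints)."""
        out = {}
        for i, (layer, key) in enumerate(self.parameters()):
            out[f"p{i:03d}_{key}"] = layer.params[key]
        return out

    def load_state(self, state: dict) -> None:
        for i, (layer, key) in enumerate(self.parameters()):
            layer.params[key] = np.asarray(state[f"p{i:03d}_{key}"], dtype=np.float32)


class Adam:
    """Adam with the standard defaults; one slot pair per parameter."""

    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for i, (layer, key) in enumerate(model.parameters()):
            self._m[i] = np.zeros_like(layer.params[key])
            self._v[i] = np.zeros_like(layer.params[key])

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, key) in enumerate(self.model.parameters()):
            g = layer.grads[key]
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            layer.params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Categorical cross-entropy loss and its gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
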
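"""Minimal layer zoo with explicit forward/backward passes.

Each layer caches what its backward pass needs; ``Sequential.backward``
returns the gradient with respect to the network input, which is how
generator gradients are routed through a frozen discriminator during
adversarial training.  Parameters live in ``layer.params`` and their
gradients, refreshed on every backward call, in ``layer.grads``.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F

DTYPE = np.float32


class Layer:
    """Base class; stateless layers only need forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": _he_init(rng, (in_features, out_features), in_features),
            "b": np.zeros(out_features, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gy):
        self.grads = {"w": self._x.T @ gy, "b": gy.sum(axis=0)}
        return gy @ self.params["w"].T


class Conv3d(Layer):
    """Strided 3D convolution (cross-correlation).

    Caches the im2col matrix from the forward pass so the weight gradient
    is a single matmul.  ``is_first=True`` marks an input layer whose
    input gradient nobody consumes; skipping it avoids the most expensive
    col2im of a classifier backward pass.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, is_first: bool = False):
        super().__init__()
        self.stride = (stride,) * 3
        self.pad = (pad,) * 3
        self.kernel = (kernel,) * 3
        self.is_first = is_first
        fan_in = in_ch * kernel ** 3
        self.params = {
            "w": _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in),
            "b": np.zeros(out_ch, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        self._xshape = x.shape
        y, self._cols = F.corr3d_with_cols(x, self.params["w"], self.stride,
                                           self.pad, keep_cols=training)
        y += self.params["b"].reshape(1, -1, 1, 1, 1)
        return y

    def backward(self, gy):
        o = gy.shape[1]
        gyr = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
        gw = (self._cols.T @ gyr).T.reshape(self.params["w"].shape)
        self.grads = {"w": gw, "b": gyr.sum(axis=0)}
        self._cols = None
        if self.is_first:
            return None
        return F.corr3d_grad_x(gy, self.params["w"], self.stride, self.pad,
                               self._xshape)


class ConvTranspose3d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        super().__init__()
        self.stride = (stride,) * 3
        self.pad = (pad,) * 3
        fan_in = in_ch * kernel ** 3
        self.params = {
            "w": _he_init(rng, (in_ch, out_ch, kernel, kernel, kernel), fan_in),
            "b": np.zeros(out_ch, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        self._x = x
        return F.conv_transpose3d(x, self.params["w"], self.stride, self.pad,
                                  self.params["b"])

    def backward(self, gy):
        gx, gw = F.conv_transpose3d_grad(self._x, gy, self.params["w"],
                                         self.stride, self.pad)
        self.grads = {"w": gw, "b": gy.sum(axis=(0, 2, 3, 4))}
        return gx


class ConvUp2(Layer):
    """Transposed convolution with kernel 2, stride 2 (learned 2x upsample).

    Because windows do not overlap, the whole layer is one matmul of the
    voxel-by-channel matrix with a (C_in, C_out*8) weight — no im2col
    duplication, which matters on memory-bandwidth-bound hosts.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = {
            "w": _he_init(rng, (in_ch, out_ch * 8), in_ch),
            "b": np.zeros(out_ch, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        xr = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1)).reshape(-1, c)
        self._xr = xr
        self._shape = x.shape
        y = xr @ self.params["w"]
        y = y.reshape(n, d, h, w, self.out_ch, 2, 2, 2)
        y = np.ascontiguousarray(y.transpose(0, 4, 1, 5, 2, 6, 3, 7))
        y = y.reshape(n, self.out_ch, 2 * d, 2 * h, 2 * w)
        return y + self.params["b"].reshape(1, -1, 1, 1, 1)

    def backward(self, gy):
        n, c, d, h, w = self._shape
        g = gy.reshape(n, self.out_ch, d, 2, h, 2, w, 2)
        g = np.ascontiguousarray(g.transpose(0, 2, 4, 6, 1, 3, 5, 7))
        g = g.reshape(-1, self.out_ch * 8)
        self.grads = {"w": self._xr.T @ g,
                      "b": gy.sum(axis=(0, 2, 3, 4))}
        gx = (g @ self.params["w"].T).reshape(n, d, h, w, c)
        return np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3))


class ConvDown2(Layer):
    """Convolution with kernel 2, stride 2 (learned 2x downsample); the
    mirror of ConvUp2, likewise a single matmul."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 is_first: bool = False):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.is_first = is_first
        self.params = {
            "w": _he_init(rng, (in_ch * 8, out_ch), in_ch * 8),
            "b": np.zeros(out_ch, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"ConvDown2 needs even spatial dims, got {(d, h, w)}")
        v = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = np.ascontiguousarray(v.transpose(0, 2, 4, 6, 1, 3, 5, 7))
        xr = v.reshape(-1, c * 8)
        self._xr = xr
        self._shape = x.shape
        y = xr @ self.params["w"] + self.params["b"]
        y = y.reshape(n, d // 2, h // 2, w // 2, self.out_ch)
        return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))

    def backward(self, gy):
        n, c, d, h, w = self._shape
        o = self.out_ch
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
        self.grads = {"w": self._xr.T @ g, "b": g.sum(axis=0)}
        if self.is_first:
            return None
        gx = (g @ self.params["w"].T).reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        gx = np.ascontiguousarray(gx.transpose(0, 4, 1, 5, 2, 6, 3, 7))
        return gx.reshape(self._shape)


class MaxPool3d(Layer):
    """2x2x2 max pooling; requires even spatial dimensions."""

    def forward(self, x, training=False):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {(d, h, w)}")
        v = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = v.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._arg = v.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, d, h, w = self._shape
        g = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(g, self._arg[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(self._shape)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, gy):
        return np.where(self._neg, self.slope * gy, gy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        # numerically stable logistic
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 60))),
                           np.exp(np.clip(x, -60, None)) /
                           (1.0 + np.exp(np.clip(x, -60, None)))).astype(x.dtype)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; the owning model supplies the RNG."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an RNG")
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization with a learned affine map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"].reshape(1, -1, 1, 1, 1) + \
            self.params["beta"].reshape(1, -1, 1, 1, 1)

    def backward(self, gy):
        ax = (2, 3, 4)
        m = gy.shape[2] * gy.shape[3] * gy.shape[4]
        self.grads = {
            "gamma": (gy * self._xhat).sum(axis=(0, 2, 3, 4)),
            "beta": gy.sum(axis=(0, 2, 3, 4)),
        }
        g = gy * self.params["gamma"].reshape(1, -1, 1, 1, 1)
        gsum = g.sum(axis=ax, keepdims=True)
        gxsum = (g * self._xhat).sum(axis=ax, keepdims=True)
        return self._inv * (g - gsum / m - self._xhat * gxsum / m)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, training=False):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(gy.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def parameters(self):
        """Flat (key, layer, name) triples in a stable order."""
        out = []
        for i, layer in enumerate(self.layers):
            for name in sorted(layer.params):
                out.append((f"{i}.{name}", layer, name))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: layer.params[name].copy()
                for key, layer, name in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            if key not in state:
                raise KeyError(f"missing parameter {key} in state dict")
            if state[key].shape != layer.params[name].shape:
                raise ValueError(f"shape mismatch for {key}")
            layer.params[name] = state[key].astype(DTYPE).copy()
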
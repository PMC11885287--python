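"""Minimal NumPy neural-network layers with manual backpropagation.

Array layout is channel-last throughout: images/feature maps are
``(N, H, W, C)`` (a single ``(H, W, C)`` input is promoted to a batch of
one), and convolution weights are indexed ``W[m, n, c, k]`` = (kernel row,
kernel col, in-channel, out-filter).  Convolution is cross-correlation, the
deep-learning convention.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError, ShapeError

__all__ = [
    "Param",
    "Module",
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "ResidualBlock",
    "conv2d",
    "max_pool",
    "residual_forward",
    "softmax_cross_entropy",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def params(self) -> list[Param]:
        return []

    def named_params(self, prefix: str = "") -> dict[str, Param]:
        return {f"{prefix}p{i}": p for i, p in enumerate(self.params())}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, shape)


def _apply_activation(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "identity":
        return z
    raise InvalidConfigError(f"unknown activation {activation!r}")


def _activation_grad(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return (z > 0.0).astype(np.float64)
    return np.ones_like(z)


class Dense(Module):
    """Affine map ``x @ W + b`` with optional ReLU."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str = "identity",
        rng: np.random.Generator | None = None,
        init_scale: float = 1.0,
    ):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_uniform(rng, (n_in, n_out), n_in) * init_scale)
        self.b = Param(np.zeros(n_out))
        self.activation = activation
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[1] != self.W.value.shape[0]:
            raise ShapeError(
                f"Dense expects input dim {self.W.value.shape[0]}, got {x.shape[1]}"
            )
        z = x @ self.W.value + self.b.value
        y = _apply_activation(z, self.activation)
        self._cache = (x, z, squeeze)
        return y[0] if squeeze else y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, squeeze = self._cache
        grad = np.asarray(grad, dtype=np.float64)
        if squeeze:
            grad = grad[None, :]
        dz = grad * _activation_grad(z, self.activation)
        self.W.grad += x.T @ dz
        self.b.grad += dz.sum(axis=0)
        dx = dz @ self.W.value.T
        return dx[0] if squeeze else dx


def _pad_amounts(size: int, kernel: int, stride: int, padding) -> tuple[int, int]:
    if padding == "same":
        out = -(-size // stride)
        total = max((out - 1) * stride + kernel - size, 0)
        return total // 2, total - total // 2
    if padding == "valid":
        return 0, 0
    return int(padding), int(padding)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding, fill=0.0):
    n, h, w, c = x.shape
    pt, pb = _pad_amounts(h, kh, stride, padding)
    pl, pr = _pad_amounts(w, kw, stride, padding)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=fill)
    hp, wp = xp.shape[1], xp.shape[2]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ShapeError(
            f"kernel ({kh}x{kw}, stride {stride}) does not fit input of "
            f"spatial shape {(h, w)}"
        )
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, oh, ow, kh, kw, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    cols = view.reshape(n * oh * ow, kh * kw * c)
    return cols, (n, oh, ow, hp, wp, pt, pl)


def _col2im(dcols, kh, kw, stride, geometry, h, w, c):
    n, oh, ow, hp, wp, pt, pl = geometry
    dxp = np.zeros((n, hp, wp, c))
    dview = dcols.reshape(n, oh, ow, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += (
                dview[:, :, :, i, j, :]
            )
    return dxp[:, pt : pt + h, pl : pl + w, :]


class Conv2d(Module):
    """2-D cross-correlation plus bias and optional ReLU."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int | tuple[int, int],
        stride: int = 1,
        padding="same",
        activation: str = "identity",
        rng: np.random.Generator | None = None,
        init_scale: float = 1.0,
    ):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw * c_in
        self.W = Param(_he_uniform(rng, (kh, kw, c_in, c_out), fan_in) * init_scale)
        self.b = Param(np.zeros(c_out))
        self.stride = stride
        self.padding = padding
        self.activation = activation
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        kh, kw, c_in, c_out = self.W.value.shape
        if x.shape[3] != c_in:
            raise ShapeError(
                f"Conv2d expects {c_in} input channels, got input shape {x.shape}"
            )
        cols, geometry = _im2col(x, kh, kw, self.stride, self.padding)
        n, oh, ow = geometry[0], geometry[1], geometry[2]
        z = cols @ self.W.value.reshape(kh * kw * c_in, c_out) + self.b.value
        z = z.reshape(n, oh, ow, c_out)
        y = _apply_activation(z, self.activation)
        self._cache = (cols, geometry, z, x.shape, squeeze)
        return y[0] if squeeze else y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, geometry, z, x_shape, squeeze = self._cache
        kh, kw, c_in, c_out = self.W.value.shape
        grad = np.asarray(grad, dtype=np.float64)
        if squeeze:
            grad = grad[None]
        dz = (grad * _activation_grad(z, self.activation)).reshape(-1, c_out)
        self.W.grad += (cols.T @ dz).reshape(self.W.value.shape)
        self.b.grad += dz.sum(axis=0)
        dcols = dz @ self.W.value.reshape(kh * kw * c_in, c_out).T
        dx = _col2im(dcols, kh, kw, self.stride, geometry, x_shape[1], x_shape[2], c_in)
        return dx[0] if squeeze else dx


class MaxPool2d(Module):
    """Per-channel max over sliding windows."""

    def __init__(self, window: int, stride: int | None = None, padding="valid"):
        self.window = window
        self.stride = stride or window
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if self.padding == "valid" and (
            x.shape[1] < self.window or x.shape[2] < self.window
        ):
            raise ShapeError(
                f"pool window {self.window} larger than input {x.shape[1:3]}"
            )
        c = x.shape[3]
        cols, geometry = _im2col(
            x, self.window, self.window, self.stride, self.padding, fill=-np.inf
        )
        n, oh, ow = geometry[0], geometry[1], geometry[2]
        patches = cols.reshape(n * oh * ow, self.window * self.window, c)
        arg = patches.argmax(axis=1)
        y = np.take_along_axis(patches, arg[:, None, :], axis=1)[:, 0, :]
        y = y.reshape(n, oh, ow, c)
        self._cache = (arg, geometry, x.shape, squeeze)
        return y[0] if squeeze else y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, geometry, x_shape, squeeze = self._cache
        grad = np.asarray(grad, dtype=np.float64)
        if squeeze:
            grad = grad[None]
        n, oh, ow = geometry[0], geometry[1], geometry[2]
        c = x_shape[3]
        dpatches = np.zeros((n * oh * ow, self.window * self.window, c))
        np.put_along_axis(dpatches, arg[:, None, :], grad.reshape(-1, 1, c), axis=1)
        dcols = dpatches.reshape(n * oh * ow, -1)
        dx = _col2im(
            dcols, self.window, self.window, self.stride, geometry,
            x_shape[1], x_shape[2], c,
        )
        return dx[0] if squeeze else dx


class GlobalAvgPool(Module):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        self._cache = (x.shape, squeeze)
        y = x.mean(axis=(1, 2))
        return y[0] if squeeze else y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, squeeze = self._cache
        grad = np.asarray(grad, dtype=np.float64)
        if squeeze:
            grad = grad[None]
        dx = np.broadcast_to(
            grad[:, None, None, :] / (shape[1] * shape[2]), shape
        ).copy()
        return dx[0] if squeeze else dx


class Flatten(Module):
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._cache)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def named_params(self, prefix: str = "") -> dict[str, Param]:
        out: dict[str, Param] = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.named_params(f"{prefix}l{i}."))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Module):
    """``y = post_activation(inner(x) + shortcut(x))``.

    ``shortcut=None`` is the identity; a projection (e.g. strided 1x1 conv)
    is required whenever the inner path changes shape.
    """

    def __init__(
        self,
        inner: Module,
        shortcut: Module | None = None,
        post_activation: str = "identity",
    ):
        self.inner = inner
        self.shortcut = shortcut
        self.post_activation = post_activation
        self._cache = None

    def params(self) -> list[Param]:
        out = list(self.inner.params())
        if self.shortcut is not None:
            out.extend(self.shortcut.params())
        return out

    def named_params(self, prefix: str = "") -> dict[str, Param]:
        out = self.inner.named_params(f"{prefix}inner.")
        if self.shortcut is not None:
            out.update(self.shortcut.named_params(f"{prefix}short."))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        fx = self.inner.forward(x)
        sx = x if self.shortcut is None else self.shortcut.forward(x)
        if fx.shape != np.shape(sx):
            raise ShapeError(
                f"residual branch shape {fx.shape} != shortcut shape {np.shape(sx)}"
            )
        z = fx + sx
        self._cache = z
        return _apply_activation(z, self.post_activation)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dz = grad * _activation_grad(self._cache, self.post_activation)
        dx = self.inner.backward(dz)
        if self.shortcut is None:
            return dx + dz
        return dx + self.shortcut.backward(dz)


def conv2d(x: np.ndarray, layer: Conv2d) -> np.ndarray:
    """Functional convolution through an existing :class:`Conv2d` layer."""
    return layer.forward(x)


def max_pool(x: np.ndarray, window: int, stride: int | None = None) -> np.ndarray:
    return MaxPool2d(window, stride).forward(x)


def residual_forward(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    return block.forward(x)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over rows; returns (loss, probabilities, dlogits)."""
    logits = np.atleast_2d(logits)
    onehot = np.atleast_2d(onehot)
    if logits.shape != onehot.shape:
        raise ShapeError(f"logits {logits.shape} vs labels {onehot.shape}")
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    dlogits = (probs - onehot) / n
    return loss, probs, dlogits
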
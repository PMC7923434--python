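"""Layers with forward passes and hand-written reverse-mode gradients.

Conventions: activations are ``float32`` arrays of shape ``(B, C, H, W)``
(or ``(B, D)`` after global pooling).  Each layer caches what its backward
pass needs during ``forward``; ``backward`` consumes the cache and returns
the gradient w.r.t. the layer input.  Calling ``backward`` twice without an
intervening ``forward`` is undefined.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: parameterless identity-ish contract."""

    def params(self) -> list[Parameter]:
        return []

    def arrays(self) -> dict[str, np.ndarray]:
        """All state (parameters and buffers) as name -> array."""
        return {}

    def load_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        own = self.arrays()
        for name, target in own.items():
            src = arrs[name]
            if src.shape != target.shape:
                raise ValueError(f"shape mismatch for {name}: {src.shape} vs {target.shape}")
            target[...] = src

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """KxK 'same' convolution (odd K): spatial dimensions are preserved.

    Implemented as K*K shifted batched matrix products over the channel
    axis, which keeps activations in their native (B, C, H, W) layout and
    avoids the large im2col transposes.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd to preserve spatial dims")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.weight = Parameter(rng.normal(0.0, scale, (out_channels, in_channels,
                                                        kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"weight": self.weight.data, "bias": self.bias.data}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        p = k // 2
        f = self.out_channels
        wgt = self.weight.data
        if k == 1:
            xf = x.reshape(b, c, h * w)
            out = np.matmul(wgt[:, :, 0, 0], xf)
            self._cache = (x, (b, c, h, w))
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            out = np.zeros((b, f, h * w), dtype=F32)
            for i in range(k):
                for j in range(k):
                    xs = np.ascontiguousarray(xp[:, :, i:i + h, j:j + w]
                                              ).reshape(b, c, h * w)
                    out += np.matmul(wgt[:, :, i, j], xs)
            self._cache = (xp, (b, c, h, w))
        out += self.bias.data[None, :, None]
        return out.reshape(b, f, h, w)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xcache, (b, c, h, w) = self._cache
        k = self.kernel_size
        p = k // 2
        f = self.out_channels
        gr = grad_out.reshape(b, f, h * w)
        self.bias.grad += gr.sum(axis=(0, 2))
        wgt = self.weight.data
        if k == 1:
            xf = xcache.reshape(b, c, h * w)
            self.weight.grad[:, :, 0, 0] += np.tensordot(gr, xf, axes=([0, 2], [0, 2]))
            dx = np.matmul(wgt[:, :, 0, 0].T, gr)
            return dx.reshape(b, c, h, w)
        gxp = np.zeros_like(xcache)
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xcache[:, :, i:i + h, j:j + w]
                                          ).reshape(b, c, h * w)
                self.weight.grad[:, :, i, j] += np.tensordot(gr, xs, axes=([0, 2], [0, 2]))
                dxs = np.matmul(wgt[:, :, i, j].T, gr).reshape(b, c, h, w)
                gxp[:, :, i:i + h, j:j + w] += dxs
        return gxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    ``train=True`` normalises with batch statistics and updates the running
    mean/variance; ``train=False`` uses the stored running statistics, which
    makes a frozen layer fully invariant during later fine-tuning.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma.data, "beta": self.beta.data,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd.astype(F32), train)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(F32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        gscale = (self.gamma.data * invstd)[None, :, None, None]
        if not train:
            # running statistics are constants
            return grad_out * gscale
        b, _, h, w = grad_out.shape
        n = b * h * w
        dxhat = grad_out * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (the only spatial downsampler used)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        win = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(b, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        self._cache = (idx, (b, c, h, w))
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        g = np.zeros((b, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(g, idx[..., None], grad_out[..., None], axis=-1)
        g = g.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(g.reshape(b, c, h, w))


class GlobalAvgPool(Layer):
    """Collapses each channel map to its mean: (B,C,H,W) -> (B,C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None] / (h * w), (b, c, h, w)).astype(F32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, init_std: float | None = None):
        rng = rng or np.random.default_rng(0)
        std = init_std if init_std is not None else np.sqrt(1.0 / in_features)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))
        self._x = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"weight": self.weight.data, "bias": self.bias.data}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for lay in self.layers for p in lay.params()]

    def arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lay in enumerate(self.layers):
            for name, arr in lay.arrays().items():
                out[f"{i}.{name}"] = arr
        return out

    def load_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.layers):
            sub = {name[len(f"{i}."):]: arr for name, arr in arrs.items()
                   if name.startswith(f"{i}.")}
            if sub:
                lay.load_arrays(sub)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad_out = lay.backward(grad_out)
        return grad_out


class ResidualBlock(Layer):
    """Identity-shortcut residual block.

    Layout conv -> BN -> ReLU -> conv -> BN, shortcut added before a final
    ReLU.  Exactly two convolutions, two batch normalizations and two ReLU
    activations; channels in == channels out so the shortcut is a plain
    addition and the spatial dimensions are untouched.
    """

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        self.channels = channels
        self.conv1 = Conv2d(channels, channels, kernel_size, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, kernel_size, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu2 = ReLU()

    def _sublayers(self) -> dict[str, Layer]:
        return {"conv1": self.conv1, "bn1": self.bn1, "conv2": self.conv2,
                "bn2": self.bn2}

    def params(self) -> list[Parameter]:
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, lay in self._sublayers().items():
            for name, arr in lay.arrays().items():
                out[f"{prefix}.{name}"] = arr
        return out

    def load_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        for prefix, lay in self._sublayers().items():
            sub = {name[len(prefix) + 1:]: arr for name, arr in arrs.items()
                   if name.startswith(prefix + ".")}
            lay.load_arrays(sub)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        return self.relu2.forward(y + x, train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(grad_out)
        gy = self.bn2.backward(g)
        gy = self.conv2.backward(gy)
        gy = self.relu1.backward(gy)
        gy = self.bn1.backward(gy)
        gy = self.conv1.backward(gy)
        return gy + g
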
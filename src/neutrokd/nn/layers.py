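"""Layer primitives with explicit forward/backward passes.

All computation is single-precision NumPy.  Every layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the cache and
returns the gradient with respect to the layer input.  Convolution uses an
im2col/GEMM formulation.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        #: whether decoupled weight decay applies (False for biases / BN)
        self.decay = decay


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    n, c, h, w = xp.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, ho, wo, k, k), (sn, sc, sh * stride, sw * stride, sh, sw)
    )


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.k, self.stride = k, stride
        self.pad = k // 2 if padding is None else padding
        # He initialization for ReLU networks
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Param(rng.normal(0.0, std, (out_channels, in_channels, k, k)))
        self.bias = Param(np.zeros(out_channels), decay=False) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _windows(xp, k, s)
        n_, _, ho, wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        cout = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout).astype(np.float32)
        self.weight.grad += (dflat.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=0)
        dcols = dflat @ self.weight.data.reshape(cout, -1)
        dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dwin[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), decay=False)
        self.beta = Param(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term * inv[None, :, None, None]


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int | None = None, padding: int = 0):
        self.k = kernel_size
        self.stride = stride or kernel_size
        self.pad = padding

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        p, k, s = self.pad, self.k, self.stride
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        )
        win = _windows(xp, k, s)
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=-1)
        self._shapes = (x.shape, xp.shape, ho, wo)
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        xshape, xpshape, ho, wo = self._shapes
        p, k, s = self.pad, self.k, self.stride
        n, c = xshape[:2]
        rows = (self._arg // k) + s * np.arange(ho)[None, None, :, None]
        cols = (self._arg % k) + s * np.arange(wo)[None, None, None, :]
        dxp = np.zeros(xpshape, dtype=np.float32)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols), dout)
        return dxp[:, :, p : p + xshape[2], p : p + xshape[3]] if p else dxp


class AvgPoolGlobal(Module):
    """Global average pooling (N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Param(np.zeros(out_features), decay=False)

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = np.ascontiguousarray(x, dtype=np.float32)
        return self._x @ self.weight.data + self.bias.data

    def backward(self, dout):
        dout = dout.astype(np.float32)
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data.T


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def params(self):
        out = []
        for m in self.layers:
            out.extend(m.params())
        return out

    def forward(self, x, train=False, record: bool = False):
        self._outs = [] if record else None
        for m in self.layers:
            x = m.forward(x, train)
            if record:
                self._outs.append(x)
        return x

    def backward(self, dout, until: int | None = None):
        """Backpropagate; with ``until=i`` stop after layer ``i`` and return
        the gradient with respect to that layer's *input*."""
        stop = 0 if until is None else until
        for i in reversed(range(stop, len(self.layers))):
            dout = self.layers[i].backward(dout)
        return dout


class BasicBlock(Module):
    """Two 3x3 convs with identity (or projected) skip connection."""

    expansion = 1

    def __init__(self, in_channels: int, channels: int, stride: int = 1, rng=None):
        self.conv1 = Conv2d(in_channels, channels, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != channels:
            self.downsample = Sequential(
                [Conv2d(in_channels, channels, 1, stride, 0, bias=False, rng=rng), BatchNorm2d(channels)]
            )
        else:
            self.downsample = None

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.downsample is not None:
            out += self.downsample.params()
        return out

    def forward(self, x, train=False):
        idn = x if self.downsample is None else self.downsample.forward(x, train)
        y = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train)), train
            ),
            train,
        )
        return self.relu_out.forward(y + idn, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        dskip = d if self.downsample is None else self.downsample.backward(d)
        return dmain + dskip


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with 4x channel expansion."""

    expansion = 4

    def __init__(self, in_channels: int, channels: int, stride: int = 1, rng=None):
        out_channels = channels * self.expansion
        self.conv1 = Conv2d(in_channels, channels, 1, 1, 0, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, stride, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(channels, out_channels, 1, 1, 0, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.downsample = Sequential(
                [Conv2d(in_channels, out_channels, 1, stride, 0, bias=False, rng=rng), BatchNorm2d(out_channels)]
            )
        else:
            self.downsample = None

    def params(self):
        out = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
            + self.conv3.params()
            + self.bn3.params()
        )
        if self.downsample is not None:
            out += self.downsample.params()
        return out

    def forward(self, x, train=False):
        idn = x if self.downsample is None else self.downsample.forward(x, train)
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, train), train))
        y = self.bn3.forward(self.conv3.forward(y, train), train)
        return self.relu_out.forward(y + idn, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dy = self.bn3.backward(d)
        dy = self.conv3.backward(dy)
        dy = self.relu2.backward(dy)
        dy = self.conv2.backward(self.bn2.backward(dy))
        dy = self.relu1.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(dy))
        dskip = d if self.downsample is None else self.downsample.backward(d)
        return dmain + dskip
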
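"""Minimal convolutional network engine (forward + backprop) in numpy.

Implements exactly the primitives the occupancy model needs:

* 1-D convolution along the sequence-position axis with same-padding and an
  arbitrary dilation rate ``l`` (taps spaced ``l`` apart:
  ``(F *_l k)(x) = sum_y F(x + l*y) k(y)``; ``l = 1`` is standard convolution);
* gated convolution ``Y = (X*W + b) . sigmoid(X*V + c)`` with paired
  feature/gate kernel stacks;
* depthwise-separable convolution (per-channel 1-D depthwise filter followed
  by a 1x1 pointwise channel mix; parameters ``K*C_in + C_in*C_out`` versus
  ``K*C_in*C_out`` for the full kernel);
* batch normalization, dropout, 1x3/stride-3 max pooling, dense layers.

Feature maps are ``(B, W, C)`` float32 arrays — batch rows, width, channels.
Because every kernel in the occupancy model is 1xK (height one), the
16-row dinucleotide axis is folded into the batch dimension by the model
wrapper, so all spatial work here is one-dimensional.

Each layer caches what its backward pass needs; ``backward`` accumulates
parameter gradients and returns the gradient with respect to its input.
Convolutions are evaluated as K shifted GEMMs rather than via an explicit
im2col buffer to keep peak memory proportional to one feature map.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param", "Layer", "Sequential", "Conv1d", "Depthwise1d", "SeparableConv1d",
    "GatedConv", "ReLU", "Sigmoid", "BatchNorm", "Dropout", "MaxPool1d",
    "Flatten", "Dense", "Parallel", "dilated_conv1d", "separable_params",
]

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=F32)
        self.g = np.zeros_like(self.v)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def n_params(self) -> int:
        return sum(p.v.size for p in self.params())


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Parallel(Layer):
    """Run branches on the same input and concatenate outputs channel-wise."""

    def __init__(self, branches: list[Layer]):
        self.branches = list(branches)
        self._splits: list[int] = []

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        self._splits = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, gy):
        gx = None
        start = 0
        for b, c in zip(self.branches, self._splits):
            g = b.backward(np.ascontiguousarray(gy[..., start:start + c]))
            gx = g if gx is None else gx + g
            start += c
        return gx

    def params(self):
        return [p for b in self.branches for p in b.params()]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv1d(Layer):
    """Same-padded 1-D convolution with dilation; weight (K, C_in, C_out).

    Evaluated as one im2col GEMM: the K dilated shifts of the padded input
    are gathered into a (B*W, K*C_in) matrix and multiplied by the weight
    reshaped to (K*C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel width must be odd and positive")
        if dilation < 1:
            raise ValueError("dilation rate must be a positive integer")
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, kernel, dilation
        self.pad = (kernel - 1) // 2 * dilation
        self.w = Param(_glorot(rng, (kernel, c_in, c_out),
                               kernel * c_in, kernel * c_out))
        self.b = Param(np.zeros(c_out)) if bias else None
        self._cols: np.ndarray | None = None

    @property
    def footprint(self) -> int:
        """Effective receptive-field width (K-1)*l + 1."""
        return (self.k - 1) * self.d + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, W, C = x.shape
        if self.k == 1:
            return x.reshape(B * W, C)
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = np.empty((B, W, self.k, C), dtype=F32)
        for i in range(self.k):
            cols[:, :, i, :] = xp[:, i * self.d:i * self.d + W, :]
        return cols.reshape(B * W, self.k * C)

    def forward(self, x, train=False):
        B, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {C}")
        cols = self._im2col(x)
        self._cols, self._shape = cols, (B, W)
        y = cols @ self.w.v.reshape(self.k * C, self.c_out)
        if self.b is not None:
            y += self.b.v
        return y.reshape(B, W, self.c_out)

    def backward(self, gy):
        B, W = self._shape
        g2 = gy.reshape(B * W, self.c_out)
        if self.b is not None:
            self.b.g += g2.sum(axis=0)
        wk = self.w.v.reshape(self.k * self.c_in, self.c_out)
        self.w.g += (self._cols.T @ g2).reshape(self.w.v.shape)
        gcols = g2 @ wk.T
        self._cols = None
        if self.k == 1:
            return gcols.reshape(B, W, self.c_in)
        gcols = gcols.reshape(B, W, self.k, self.c_in)
        gxp = np.zeros((B, W + 2 * self.pad, self.c_in), dtype=F32)
        for i in range(self.k):
            gxp[:, i * self.d:i * self.d + W, :] += gcols[:, :, i, :]
        return gxp[:, self.pad:self.pad + W, :]

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class Depthwise1d(Layer):
    """Per-channel 1-D filter (one K-tap kernel per input channel, no mixing)."""

    def __init__(self, c: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel width must be odd and positive")
        if dilation < 1:
            raise ValueError("dilation rate must be a positive integer")
        rng = rng or np.random.default_rng()
        self.c, self.k, self.d = c, kernel, dilation
        self.pad = (kernel - 1) // 2 * dilation
        self.w = Param(_glorot(rng, (kernel, c), kernel, kernel))

    def forward(self, x, train=False):
        B, W, C = x.shape
        if C != self.c:
            raise ValueError(f"expected {self.c} channels, got {C}")
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0))) \
            if self.pad else x
        self._xp, self._W = xp, W
        y = np.zeros_like(x)
        for i in range(self.k):
            y += xp[:, i * self.d:i * self.d + W, :] * self.w.v[i]
        return y

    def backward(self, gy):
        B, W, C = gy.shape
        gxp = np.zeros_like(self._xp)
        for i in range(self.k):
            seg = self._xp[:, i * self.d:i * self.d + W, :]
            self.w.g[i] += np.einsum("bwc,bwc->c", seg, gy)
            gxp[:, i * self.d:i * self.d + W, :] += gy * self.w.v[i]
        self._xp = None
        return gxp[:, self.pad:self.pad + W, :] if self.pad else gxp

    def params(self):
        return [self.w]


class SeparableConv1d(Sequential):
    """Depthwise 1-D filter followed by a 1x1 pointwise channel mix.

    Bias lives on the pointwise stage only, so the trainable weight count is
    K*C_in (depthwise) + C_in*C_out (pointwise) + C_out (bias).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        depthwise = Depthwise1d(c_in, kernel, dilation, rng=rng)
        pointwise = Conv1d(c_in, c_out, 1, bias=bias, rng=rng)
        super().__init__([depthwise, pointwise])
        self.footprint = depthwise.pad * 2 + 1


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = expit(x).astype(F32)
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class GatedConv(Layer):
    """Gated convolution: Y = (X*W + b) . sigmoid(X*V + c).

    The feature path (kernel W, bias b) and gate path (kernel V, bias c) have
    identical shapes; the sigmoid gate adaptively scales each feature.  With
    ``separable=True`` both paths are depthwise-separable stacks.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 separable: bool = False, rng: np.random.Generator | None = None):
        self.c_out = c_out
        self.separable = separable and kernel > 1
        if self.separable:
            self.feature = SeparableConv1d(c_in, c_out, kernel, dilation,
                                           bias=True, rng=rng)
            self.gate = SeparableConv1d(c_in, c_out, kernel, dilation,
                                        bias=True, rng=rng)
        else:
            # feature and gate share one im2col: a single conv computes both
            # stacks (first c_out channels = feature path W,b; last c_out =
            # gate path V,c); parameter count is unchanged.
            self.fused = Conv1d(c_in, 2 * c_out, kernel, dilation, bias=True,
                                rng=rng)

    # views of the paired parameter stacks (Eq. symbols W, b, V, c)
    @property
    def w_feature(self):
        return self.fused.w.v[..., :self.c_out]

    @property
    def w_gate(self):
        return self.fused.w.v[..., self.c_out:]

    @property
    def b_feature(self):
        return self.fused.b.v[:self.c_out]

    @property
    def b_gate(self):
        return self.fused.b.v[self.c_out:]

    def forward(self, x, train=False):
        if self.separable:
            f = self.feature.forward(x, train)
            s = expit(self.gate.forward(x, train)).astype(F32)
        else:
            both = self.fused.forward(x, train)
            f = both[..., :self.c_out]
            s = expit(both[..., self.c_out:]).astype(F32)
        self._f, self._s = f, s
        return f * s

    def backward(self, gy):
        gf = gy * self._s
        gg = gy * self._f * self._s * (1.0 - self._s)
        self._f = self._s = None
        if self.separable:
            return self.feature.backward(gf) + self.gate.backward(gg)
        return self.fused.backward(np.concatenate([gf, gg], axis=-1))

    def params(self):
        if self.separable:
            return self.feature.params() + self.gate.params()
        return self.fused.params()


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        flat = x.reshape(-1, x.shape[-1])
        if train:
            n = flat.shape[0]
            mean = flat.mean(axis=0, dtype=np.float64)
            var = np.maximum(
                np.einsum("nc,nc->c", flat, flat, dtype=np.float64) / n
                - mean ** 2, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        mean = mean.astype(F32)
        # y = a*x + shift, a = gamma*invstd, shift = beta - mean*a
        a = self.gamma.v * invstd
        self._x, self._mean, self._invstd, self._train = x, mean, invstd, train
        return x * a + (self.beta.v - mean * a)

    def backward(self, gy):
        c = gy.shape[-1]
        flat_g = gy.reshape(-1, c)
        xhat = ((self._x - self._mean) * self._invstd)
        flat_xhat = xhat.reshape(-1, c)
        gsum = flat_g.sum(axis=0)
        gxsum = np.einsum("nc,nc->c", flat_g, flat_xhat)
        self.gamma.g += gxsum
        self.beta.g += gsum
        if not self._train:
            self._x = None
            return (gy * (self.gamma.v * self._invstd)).astype(F32, copy=False)
        n = flat_g.shape[0]
        dx = (gy * self.gamma.v
              - (self.gamma.v * gsum) / n
              - xhat * ((self.gamma.v * gxsum) / n)) * self._invstd
        self._x = None
        return dx.astype(F32, copy=False)

    def params(self):
        return [self.gamma, self.beta]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = F32(1.0 - self.rate)
        mask = (self.rng.random(x.shape, dtype=F32) < keep).astype(F32)
        mask /= keep
        self._mask = mask
        return x * mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool1d(Layer):
    """Valid max pooling along the width axis (default 1x3, stride 3)."""

    def __init__(self, width: int = 3, stride: int = 3):
        if width != stride:
            raise NotImplementedError("only non-overlapping pooling supported")
        self.width = width

    @staticmethod
    def out_width(w: int, width: int = 3) -> int:
        return (w - width) // width + 1

    def forward(self, x, train=False):
        B, W, C = x.shape
        n = self.out_width(W, self.width)
        if n < 1:
            raise ValueError(f"width {W} too small for pooling window {self.width}")
        r = x[:, :n * self.width, :].reshape(B, n, self.width, C)
        self._arg = r.argmax(axis=2)
        self._shape = x.shape
        return r.max(axis=2)

    def backward(self, gy):
        B, n, C = gy.shape
        gr = np.zeros((B, n, self.width, C), dtype=F32)
        np.put_along_axis(gr, self._arg[:, :, None, :], gy[:, :, None, :], axis=2)
        gx = np.zeros(self._shape, dtype=F32)
        gx[:, :n * self.width, :] = gr.reshape(B, n * self.width, C)
        return gx


class Flatten(Layer):
    """(N*height, W, C) -> (N, height*W*C): undo the folded-row layout."""

    def __init__(self, height: int):
        self.height = height

    def forward(self, x, train=False):
        Bh, W, C = x.shape
        if Bh % self.height:
            raise ValueError("batch axis is not a multiple of the map height")
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(Bh // self.height,
                                               self.height * W * C)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.v + self.b.v

    def backward(self, gy):
        self.w.g += self._x.T @ gy
        self.b.g += gy.sum(axis=0)
        self._x = None
        return gy @ self.w.v.T

    def params(self):
        return [self.w, self.b]


# ---------------------------------------------------------------------------
# Functional forms used directly in analyses and oracle checks

def dilated_conv1d(f: np.ndarray, kernel: np.ndarray, dilation: int = 1,
                   padding: str = "valid") -> np.ndarray:
    """1-D dilated convolution of a signal with a K-tap kernel.

    ``out[x] = sum_y f[x + dilation*y] * kernel[y]`` over valid taps; with
    ``padding='same'`` the signal is zero-padded so the output length equals
    the input length (kernel centered, odd K).
    """
    f = np.asarray(f, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if dilation < 1:
        raise ValueError("dilation rate must be a positive integer")
    k = kernel.size
    if padding == "same":
        if k % 2 == 0:
            raise ValueError("same-padding requires an odd kernel")
        pad = (k - 1) // 2 * dilation
        f = np.pad(f, (pad, pad))
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    n = f.size - (k - 1) * dilation
    if n < 1:
        raise ValueError("signal shorter than the dilated kernel footprint")
    out = np.zeros(n)
    for y in range(k):
        out += f[y * dilation:y * dilation + n] * kernel[y]
    return out


def separable_params(kernel: int, c_in: int, c_out: int,
                     spatial_dims: int = 1) -> dict[str, int]:
    """Weight counts of a depthwise-separable vs. full convolution.

    ``spatial_dims=2`` gives the square-kernel form (depthwise K^2*C_in);
    ``spatial_dims=1`` the 1xK form used here (depthwise K*C_in).  Pointwise
    is C_in*C_out in both.  Bias terms are excluded.
    """
    if min(kernel, c_in, c_out, spatial_dims) < 1 or spatial_dims > 2:
        raise ValueError("kernel, channel counts positive; spatial_dims in {1,2}")
    taps = kernel ** spatial_dims
    depthwise = taps * c_in
    pointwise = c_in * c_out
    return {
        "depthwise": depthwise,
        "pointwise": pointwise,
        "separable_total": depthwise + pointwise,
        "full": taps * c_in * c_out,
    }
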
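"""Layer modules built on the functional ops."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .core import Module, Parameter, Tensor, _make


def he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1 - self.momentum
            # unbiased estimate feeds the running variance, as is conventional
            self.running_var += self.momentum * var * n / max(n - 1, 1)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        mean4 = mean.reshape(1, -1, 1, 1)
        invstd4 = invstd.reshape(1, -1, 1, 1)
        xhat = (x.data - mean4) * invstd4
        out_data = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta.accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gscaled = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    n = g.shape[0] * g.shape[2] * g.shape[3]
                    sum_g = gscaled.sum(axis=(0, 2, 3), keepdims=True)
                    sum_gx = (gscaled * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = invstd4 * (gscaled - sum_g / n - xhat * sum_gx / n)
                else:
                    dx = gscaled * invstd4
                x.accumulate(dx)

        return _make(out_data, (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Upsample2x(Module):
    """Bilinear x2 upsampling (half-pixel-centres convention)."""

    def forward(self, x):
        _, _, h, w = x.data.shape
        return F.upsample_bilinear(x, 2 * h, 2 * w)


class CoordinateAttention(Module):
    """Coordinate attention: channel attention factorized along H and W.

    Spatial context is pooled separately along each coordinate axis,
    squeezed through a shared 1x1 bottleneck, and expanded into two
    sigmoid gates that recalibrate the input.
    """

    def __init__(self, c, reduction=16, rng=None):
        super().__init__()
        mip = max(8, c // reduction)
        self.conv_squeeze = Conv2d(c, mip, 1, pad=0, rng=rng)
        self.bn = BatchNorm2d(mip)
        self.relu = ReLU()
        self.conv_h = Conv2d(mip, c, 1, pad=0, bias=True, rng=rng)
        self.conv_w = Conv2d(mip, c, 1, pad=0, bias=True, rng=rng)

    def forward(self, x):
        _, _, h, w = x.data.shape
        ph = F.mean(x, axis=3, keepdims=True)              # (B, C, H, 1)
        pw = F.swap_hw(F.mean(x, axis=2, keepdims=True))   # (B, C, W, 1)
        y = F.concat([ph, pw], axis=2)                     # (B, C, H+W, 1)
        y = self.relu(self.bn(self.conv_squeeze(y)))
        ah = F.sigmoid(self.conv_h(F.narrow(y, 2, 0, h)))          # (B, C, H, 1)
        aw = F.sigmoid(self.conv_w(F.swap_hw(F.narrow(y, 2, h, w))))  # (B, C, 1, W)
        return F.mul(F.mul(x, ah), aw)
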
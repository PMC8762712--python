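"""Residual network blocks (basic, pyramid, bottleneck, inverted-residual, FP).

Each block is a :class:`fpnets.nn.Layer` operating on NCHW batches.  The
FP-block layer is the trainable counterpart of the functional operations in
:mod:`fpnets.fp_block`: 1x1 expansion + ReLU, two depthwise 3x3 filter banks
each followed by instance normalisation and ReLU, elementwise product, 1x1
projection, and an identity residual only when input and output shapes match.
Convolutions carry no bias and the block interior has no batch
normalisation, which is what makes its parameter arithmetic exact.
"""

from __future__ import annotations

import numpy as np

from .nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, InstanceNorm2d, Layer,
                 ReLU, ReLU6, Sequential)

__all__ = ["BasicBlock", "PyramidBlock", "BottleneckBlock",
           "InvertedResidualBlock", "FPBlockLayer"]


class _ResidualBlock(Layer):
    """Main path plus identity / projection / absent shortcut."""

    def __init__(self, main: Sequential, shortcut, post_relu: bool):
        self.main = main
        self.shortcut = shortcut  # "identity" | "none" | Sequential
        self.post = ReLU() if post_relu else None

    def forward(self, x, train=False):
        y = self.main.forward(x, train=train)
        if self.shortcut == "identity":
            y = y + x
        elif isinstance(self.shortcut, Sequential):
            y = y + self.shortcut.forward(x, train=train)
        if self.post is not None:
            y = self.post.forward(x=y, train=train)
        return y

    def backward(self, dy):
        if self.post is not None:
            dy = self.post.backward(dy)
        dx = self.main.backward(dy)
        if self.shortcut == "identity":
            dx = dx + dy
        elif isinstance(self.shortcut, Sequential):
            dx = dx + self.shortcut.backward(dy)
        return dx


class BasicBlock(_ResidualBlock):
    """conv3-BN-ReLU-conv3-BN with post-addition ReLU (classic ResNet)."""

    def __init__(self, d_in, d_out, stride=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        main = Sequential(
            Conv2d(d_in, d_out, 3, stride, rng=rng, dtype=dtype), BatchNorm2d(d_out, dtype=dtype), ReLU(),
            Conv2d(d_out, d_out, 3, 1, rng=rng, dtype=dtype), BatchNorm2d(d_out, dtype=dtype))
        if stride != 1 or d_in != d_out:
            shortcut = Sequential(Conv2d(d_in, d_out, 1, stride, pad=0, rng=rng, dtype=dtype),
                                  BatchNorm2d(d_out, dtype=dtype))
        else:
            shortcut = "identity"
        super().__init__(main, shortcut, post_relu=True)


class PyramidBlock(_ResidualBlock):
    """BN-conv3-BN-ReLU-conv3-BN, no post-addition ReLU (pyramid variant)."""

    def __init__(self, d_in, d_out, stride=1, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        main = Sequential(
            BatchNorm2d(d_in, dtype=dtype),
            Conv2d(d_in, d_out, 3, stride, rng=rng, dtype=dtype), BatchNorm2d(d_out, dtype=dtype), ReLU(),
            Conv2d(d_out, d_out, 3, 1, rng=rng, dtype=dtype), BatchNorm2d(d_out, dtype=dtype))
        if stride != 1 or d_in != d_out:
            shortcut = Sequential(Conv2d(d_in, d_out, 1, stride, pad=0, rng=rng, dtype=dtype),
                                  BatchNorm2d(d_out, dtype=dtype))
        else:
            shortcut = "identity"
        super().__init__(main, shortcut, post_relu=False)


class BottleneckBlock(_ResidualBlock):
    """1x1 reduce, 3x3, 1x1 expand (ResNet-50 style); stride on the 3x3."""

    def __init__(self, d_in, d_out, stride=1, mid=None, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        mid = mid if mid is not None else d_out // 4
        main = Sequential(
            Conv2d(d_in, mid, 1, 1, pad=0, rng=rng, dtype=dtype), BatchNorm2d(mid, dtype=dtype), ReLU(),
            Conv2d(mid, mid, 3, stride, rng=rng, dtype=dtype), BatchNorm2d(mid, dtype=dtype), ReLU(),
            Conv2d(mid, d_out, 1, 1, pad=0, rng=rng, dtype=dtype), BatchNorm2d(d_out, dtype=dtype))
        if stride != 1 or d_in != d_out:
            shortcut = Sequential(Conv2d(d_in, d_out, 1, stride, pad=0, rng=rng, dtype=dtype),
                                  BatchNorm2d(d_out, dtype=dtype))
        else:
            shortcut = "identity"
        super().__init__(main, shortcut, post_relu=True)


class InvertedResidualBlock(_ResidualBlock):
    """MobileNet-V2 block: 1x1 expand, depthwise 3x3, 1x1 project (linear)."""

    def __init__(self, d_in, d_out, stride=1, t=6, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        hidden = d_in * t
        layers = []
        if t != 1:
            layers += [Conv2d(d_in, hidden, 1, 1, pad=0, rng=rng, dtype=dtype),
                       BatchNorm2d(hidden, dtype=dtype), ReLU6()]
        layers += [DepthwiseConv2d(hidden, 3, stride, rng=rng, dtype=dtype),
                   BatchNorm2d(hidden, dtype=dtype), ReLU6(),
                   Conv2d(hidden, d_out, 1, 1, pad=0, rng=rng, dtype=dtype),
                   BatchNorm2d(d_out, dtype=dtype)]
        shortcut = "identity" if (stride == 1 and d_in == d_out) else "none"
        super().__init__(Sequential(*layers), shortcut, post_relu=False)


class FPBlockLayer(Layer):
    """Trainable FP-block with ``round(q * d_out)`` feature-product units.

    Set ``capture`` to record the T2 tensor (the FP-unit responses) on the
    next forward pass in ``last_t2``; filter pairs are exposed through
    ``filters_v`` / ``filters_g`` for the neuron analyses.
    """

    def __init__(self, d_in, d_out, stride=1, q=1.0, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_out, self.stride, self.q = d_in, d_out, stride, q
        self.n_pairs = int(round(q * d_out))
        e = self.n_pairs
        self.expand = Conv2d(d_in, e, 1, 1, pad=0, rng=rng, dtype=dtype)
        self.relu_in = ReLU()
        self.dw_v = DepthwiseConv2d(e, 3, stride, rng=rng, dtype=dtype)
        self.dw_g = DepthwiseConv2d(e, 3, stride, rng=rng, dtype=dtype)
        self.in_v = InstanceNorm2d()
        self.in_g = InstanceNorm2d()
        self.relu_v = ReLU()
        self.relu_g = ReLU()
        self.project = Conv2d(e, d_out, 1, 1, pad=0, rng=rng, dtype=dtype)
        self.residual = (stride == 1 and d_in == d_out)
        self.capture = False
        self.last_t2 = None
        self._cache = None

    @property
    def filters_v(self) -> np.ndarray:
        return self.dw_v.W.value

    @property
    def filters_g(self) -> np.ndarray:
        return self.dw_g.W.value

    def forward(self, x, train=False):
        t1 = self.relu_in.forward(self.expand.forward(x, train), train)
        bv = self.relu_v.forward(self.in_v.forward(self.dw_v.forward(t1, train), train), train)
        bg = self.relu_g.forward(self.in_g.forward(self.dw_g.forward(t1, train), train), train)
        t2 = bv * bg
        if self.capture:
            self.last_t2 = t2.copy()
        y = self.project.forward(t2, train)
        self._cache = (bv, bg)
        if self.residual:
            y = y + x
        return y

    def backward(self, dy):
        bv, bg = self._cache
        self._cache = None
        dt2 = self.project.backward(dy)
        dbv = dt2 * bg
        dbg = dt2 * bv
        dt1 = self.dw_v.backward(self.in_v.backward(self.relu_v.backward(dbv)))
        dt1 = dt1 + self.dw_g.backward(self.in_g.backward(self.relu_g.backward(dbg)))
        dx = self.expand.backward(self.relu_in.backward(dt1))
        if self.residual:
            dx = dx + dy
        return dx
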
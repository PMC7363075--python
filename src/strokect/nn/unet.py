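"""Encoder-decoder segmentation network with skip connections.

Dimensionality-generic: the same class implements the slice-wise (2D,
5x5 kernels) and volumetric (3D, 3x3x3 kernels) variants. The final
layer is a 1-kernel convolution producing one logit per voxel; callers
apply a sigmoid to obtain probabilities.
"""
from __future__ import annotations

import numpy as np

from .layers import Conv, Module
from .tensor import Tensor, concat, conv_nd, maxpool_nd, relu, sigmoid, upsample_nd


class UNet(Module):
    """U-Net with two convolutions per level and factor-2 pooling.

    ``filters`` lists the channel widths per level; the last entry is the
    bottleneck, so ``len(filters) - 1`` poolings are applied. Every spatial
    input dimension must be divisible by ``2 ** (len(filters) - 1)``.
    """

    def __init__(self, in_ch: int, filters, kernel, input_size, seed: int):
        self.filters = tuple(filters)
        self.kernel = tuple(kernel)
        self.input_size = tuple(input_size)
        depth = len(self.filters) - 1
        if depth < 1:
            raise ValueError("need at least two filter widths (encoder + bottleneck)")
        div = 2 ** depth
        if any(s % div for s in self.input_size):
            raise ValueError(
                f"input size {self.input_size} not divisible by pooling factor {div}")
        rng = np.random.default_rng(seed)
        nd = len(self.kernel)
        self.enc: list[list[Conv]] = []
        ch = in_ch
        for f in self.filters[:-1]:
            self.enc.append([Conv(ch, f, self.kernel, rng), Conv(f, f, self.kernel, rng)])
            ch = f
        fb = self.filters[-1]
        self.bottleneck = [Conv(ch, fb, self.kernel, rng), Conv(fb, fb, self.kernel, rng)]
        self.dec: list[list[Conv]] = []
        ch = fb
        for f in reversed(self.filters[:-1]):
            self.dec.append([Conv(ch + f, f, self.kernel, rng), Conv(f, f, self.kernel, rng)])
            ch = f
        self.head = Conv(ch, 1, (1,) * nd, rng)
        self._pool = (2,) * nd

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for c1, c2 in self.enc:
            x = relu(c2(relu(c1(x))))
            skips.append(x)
            x = maxpool_nd(x, self._pool)
        c1, c2 = self.bottleneck
        x = relu(c2(relu(c1(x))))
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            x = upsample_nd(x, self._pool)
            x = concat([skip, x], axis=1)
            x = relu(c2(relu(c1(x))))
        return self.head(x)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a (N, *spatial) batch."""
        x = Tensor(batch[:, None].astype(np.float32))
        return sigmoid(self.forward(x)).data[:, 0]
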
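"""Dual-pathway densely connected 3D classifier for border patches.

Two identical-topology pathways process the fine and the coarse patch.
Each pathway stacks dense blocks (every convolution sees the channel
concatenation of all previous outputs in its block; 3x3x3 kernels) and
transition blocks (1x1x1 channel-compressing convolution followed by
in-plane max pooling and dropout). Pathway outputs are merged before the
fully connected head, which ends in a 2-unit softmax.
"""
from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv, Dense, Dropout, Module
from .tensor import Tensor, concat, maxpool_nd, relu, reshape, softmax


class _DenseBlock(Module):
    def __init__(self, in_ch: int, n_layers: int, growth: int,
                 rng: np.random.Generator, bn_momentum: float, bn_eps: float):
        self.bns: list[BatchNorm] = []
        self.convs: list[Conv] = []
        ch = in_ch
        for _ in range(n_layers):
            self.bns.append(BatchNorm(ch, bn_momentum, bn_eps))
            self.convs.append(Conv(ch, growth, (3, 3, 3), rng))
            ch += growth
        self.out_ch = ch

    def forward(self, x: Tensor, training: bool) -> Tensor:
        for bn, conv in zip(self.bns, self.convs):
            y = conv(relu(bn(x, training)))
            x = concat([x, y], axis=1)
        return x


class _Transition(Module):
    def __init__(self, in_ch: int, compression: float, dropout_rate: float,
                 rng: np.random.Generator):
        self.out_ch = max(1, int(in_ch * compression))
        self.conv = Conv(in_ch, self.out_ch, (1, 1, 1), rng)
        self.drop = Dropout(dropout_rate)

    def forward(self, x: Tensor, rng, training: bool) -> Tensor:
        x = maxpool_nd(relu(self.conv(x)), (1, 2, 2))
        return self.drop(x, rng, training)


class _Pathway(Module):
    def __init__(self, stem_filters: int, blocks: int, layers_per_block: int,
                 growth: int, compression: float, dropout_rate: float,
                 rng: np.random.Generator, bn_momentum: float, bn_eps: float):
        self.stem = Conv(1, stem_filters, (3, 3, 3), rng)
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        ch = stem_filters
        for _ in range(blocks):
            blk = _DenseBlock(ch, layers_per_block, growth, rng, bn_momentum, bn_eps)
            tr = _Transition(blk.out_ch, compression, dropout_rate, rng)
            self.blocks.append(blk)
            self.transitions.append(tr)
            ch = tr.out_ch
        self.out_ch = ch

    def forward(self, x: Tensor, rng, training: bool) -> Tensor:
        x = relu(self.stem(x))
        for blk, tr in zip(self.blocks, self.transitions):
            x = blk(x, training)
            x = tr(x, rng, training)
        return x


class DualPathwayDenseNet(Module):
    """Classifier over (fine, coarse) 3x32x32 patch pairs."""

    def __init__(self, stem_filters: int = 8, blocks: int = 2,
                 layers_per_block: int = 2, growth: int = 6,
                 compression: float = 0.5, dropout_rate: float = 0.2,
                 hidden_units: int = 32, bn_momentum: float = 0.99,
                 bn_eps: float = 1e-3, seed: int = 0):
        if blocks < 1 or layers_per_block < 1 or growth < 1:
            raise ValueError("blocks, layers_per_block and growth must be >= 1")
        rng = np.random.default_rng(seed)
        args = (stem_filters, blocks, layers_per_block, growth, compression,
                dropout_rate, rng, bn_momentum, bn_eps)
        self.fine_path = _Pathway(*args)
        self.coarse_path = _Pathway(*args)
        spatial = 3 * (32 // 2 ** blocks) ** 2
        feat = (self.fine_path.out_ch + self.coarse_path.out_ch) * spatial
        self.fc1 = Dense(feat, hidden_units, rng)
        self.drop = Dropout(dropout_rate)
        self.fc2 = Dense(hidden_units, 2, rng)

    def forward(self, fine: Tensor, coarse: Tensor, rng=None, training: bool = False) -> Tensor:
        if rng is None:
            rng = np.random.default_rng(0)  # unused when not training
        a = self.fine_path(fine, rng, training)
        b = self.coarse_path(coarse, rng, training)
        x = concat([a, b], axis=1)
        x = reshape(x, (x.shape[0], -1))
        x = relu(self.fc1(x))
        x = self.drop(x, rng, training)
        return self.fc2(x)  # logits; softmax applied by caller

    def predict_proba(self, fine: np.ndarray, coarse: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (N, 2); column 1 is the stroke class."""
        logits = self.forward(Tensor(fine[:, None]), Tensor(coarse[:, None]),
                              training=False)
        return softmax(logits, axis=1).data
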
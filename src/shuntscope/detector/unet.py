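"""Plain 2D U-Net: encoder/decoder with skip connections.

With feature widths ``(f1, ..., fL)`` the net has L resolution levels:
each encoder level applies ``convs_per_block`` 3x3 conv+ReLU pairs and
max-pools; the decoder mirrors it with 2x2 transposed convolutions and
skip concatenation.  A final 1x1 convolution emits one logit per pixel.
"""

from __future__ import annotations

import numpy as np

from .layers import (Adam, Conv1x1, Conv3x3, ConvT2x2, Layer, MaxPool2, ReLU)

__all__ = ["UNet2D"]


class _ConvBlock:
    def __init__(self, cin: int, cout: int, n_convs: int,
                 rng: np.random.Generator):
        self.layers: list[Layer] = []
        c = cin
        for _ in range(n_convs):
            self.layers += [Conv3x3(c, cout, rng), ReLU()]
            c = cout

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet2D:
    """U-Net mapping (B, N, N, cin) -> per-pixel logits (B, N, N, 1)."""

    def __init__(self, in_channels: int, features: tuple[int, ...],
                 n_convs: int = 2, seed: int = 0,
                 rng: np.random.Generator | None = None):
        if len(features) < 1:
            raise ValueError("need at least one feature width")
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.features = tuple(features)
        self.depth = len(features)
        self.enc: list[_ConvBlock] = []
        self.pools: list[MaxPool2] = []
        c = in_channels
        for f in features[:-1]:
            self.enc.append(_ConvBlock(c, f, n_convs, rng))
            self.pools.append(MaxPool2())
            c = f
        self.bottleneck = _ConvBlock(c, features[-1], n_convs, rng)
        self.ups: list[ConvT2x2] = []
        self.dec: list[_ConvBlock] = []
        c = features[-1]
        for f in reversed(features[:-1]):
            self.ups.append(ConvT2x2(c, f, rng))
            self.dec.append(_ConvBlock(2 * f, f, n_convs, rng))
            c = f
        self.head = Conv1x1(c, 1, rng)
        self._skip_channels: list[int] = []

    # ---------------------------------------------------------------- api
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc:
            out += blk.layers
        out += self.bottleneck.layers
        for up, blk in zip(self.ups, self.dec):
            out.append(up)
            out += blk.layers
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    def check_input(self, n: int) -> None:
        div = 2 ** (self.depth - 1)
        if n % div:
            raise ValueError(
                f"input size {n} not divisible by 2^(depth-1) = {div}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.check_input(x.shape[1])
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = blk.forward(x, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dlogits)
        # decoder stages in reverse use the shallowest skip first
        dskips = []
        for up, blk, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                   self._skip_channels):
            dy = blk.backward(dy)
            dskips.append(dy[..., :c_skip])
            dy = up.backward(dy[..., c_skip:])
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = blk.backward(dy)
        return dy
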
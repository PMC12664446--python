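"""Hierarchical multiscale ("patchwork") wrapper around plain U-Nets.

A pyramid of S scales shares one fixed matrix size.  Scale 0 sees the
whole frame; scale s sees the frame as a grid of 2^s x 2^s nested patches
of decreasing physical size, each resampled to the fixed matrix.  Every
scale runs its own U-Net; from scale 1 on, the previous scale's
full-frame probability map is cropped to the patch, resampled, and
concatenated to the patch intensities as a conditioning channel (treated
as a constant during backprop).  The finest scale's stitched map is the
model output.

Resampling uses pixel replication upward and mean pooling downward, an
exactly invertible pair on piecewise-constant maps.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tile_frames", "stitch_tiles", "upsample", "downsample"]


def upsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Replicate pixels of (B, h, w, C) by an integer factor."""
    if factor == 1:
        return x
    return np.repeat(np.repeat(x, factor, axis=1), factor, axis=2)


def downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool (B, H, W, C) by an integer factor."""
    if factor == 1:
        return x
    b, h, w, c = x.shape
    return x.reshape(b, h // factor, factor, w // factor, factor, c) \
            .mean(axis=(2, 4))


def tile_frames(x: np.ndarray, scale: int) -> np.ndarray:
    """Split (B, N, N, C) into the 4^s patches of scale ``s``, upsampled.

    Returns (B * 4^s, N, N, C); patch order is row-major within each frame.
    """
    if scale == 0:
        return x
    g = 2 ** scale
    b, n, _, c = x.shape
    p = n // g
    tiles = x.reshape(b, g, p, g, p, c).transpose(0, 1, 3, 2, 4, 5) \
             .reshape(b * g * g, p, p, c)
    return upsample(tiles, g)


def stitch_tiles(y: np.ndarray, scale: int, batch: int) -> np.ndarray:
    """Inverse of :func:`tile_frames` for per-patch maps (B*4^s, N, N, C)."""
    if scale == 0:
        return y
    g = 2 ** scale
    n = y.shape[1]
    p = n // g
    small = downsample(y, g)                       # (B*g*g, p, p, C)
    c = small.shape[-1]
    return small.reshape(batch, g, g, p, p, c).transpose(0, 1, 3, 2, 4, 5) \
                .reshape(batch, n, n, c)
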
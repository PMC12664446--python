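"""Detector configuration, training loop, inference and persistence."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .layers import Adam, bce_with_logits, sigmoid
from .patchwork import stitch_tiles, tile_frames
from .unet import UNet2D

__all__ = ["DetectorConfig", "DetectorModel", "build_model", "train",
           "predict", "predict_batch", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class DetectorConfig:
    """Hyperparameters of the multiscale obstruction detector.

    Defaults follow the reference setup: fixed 128x128 matrix at every
    scale, a scale pyramid of depth four, U-Net feature widths
    (32, 32, 64, 64, 128), Adam at rate 0.001, batch size 32, binary
    cross-entropy.  ``pyramid_depth=1`` disables the multiscale wrapper
    and leaves a plain U-Net.  ``crop_size`` optionally trains the
    (single-scale) net on random square crops to cut the cost per
    gradient step.
    """

    matrix: int = 128
    pyramid_depth: int = 4
    features: tuple[int, ...] = (32, 32, 64, 64, 128)
    convs_per_block: int = 2
    lr: float = 1e-3
    batch_size: int = 32
    loss: str = "bce"
    max_epochs: int = 40
    patience: int = 5
    min_delta: float = 1e-4
    seed: int = 0
    crop_size: int | None = None
    crop_positive_frac: float = 0.5
    input_transform: str = "linear"

    def __post_init__(self) -> None:
        if self.pyramid_depth < 1:
            raise ValueError("pyramid depth must be >= 1")
        if not self.features:
            raise ValueError("need at least one feature width")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy is supported")
        div = 2 ** (len(self.features) - 1)
        finest = self.matrix // 2 ** (self.pyramid_depth - 1)
        if self.matrix % 2 ** (self.pyramid_depth - 1):
            raise ValueError("matrix size not divisible by the patch grid")
        if self.matrix % div:
            raise ValueError(
                f"matrix size {self.matrix} not divisible by 2^(U-Net depth-1)"
                f" = {div}")
        if finest < div:
            raise ValueError("finest patch smaller than the U-Net's receptive"
                             " stride; reduce pyramid_depth or features")
        if self.crop_size is not None:
            if self.pyramid_depth != 1:
                raise ValueError("crop training requires pyramid_depth == 1")
            if self.crop_size % div or not 0 < self.crop_size <= self.matrix:
                raise ValueError("invalid crop_size")
        if not 0 <= self.crop_positive_frac <= 1:
            raise ValueError("crop_positive_frac must lie in [0, 1]")
        if self.input_transform not in ("linear", "log"):
            raise ValueError("input_transform must be 'linear' or 'log'")

    @property
    def patch_sizes(self) -> tuple[int, ...]:
        """Physical patch edge (pixels of the frame) per scale, decreasing."""
        return tuple(self.matrix // 2 ** s for s in range(self.pyramid_depth))


class DetectorModel:
    """A pyramid of U-Nets plus input-normalization state."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.scales: list[UNet2D] = []
        for s in range(config.pyramid_depth):
            rng = np.random.default_rng([config.seed, s])
            in_ch = 1 if s == 0 else 2
            self.scales.append(UNet2D(in_ch, config.features,
                                      config.convs_per_block, rng=rng))
        self.norm_offset = 0.0
        self.loss_trace: list[float] = []

    def _transform(self, images: np.ndarray) -> np.ndarray:
        """Map normalized counts to the network's input representation.

        The default log transform converts transmission to an estimated
        optical depth, -log(counts/N0 + eps), so a deposition's signal is
        an additive bump of nearly constant height regardless of how much
        material lies in front of it; the linear option feeds counts/N0
        directly.
        """
        x = np.asarray(images, dtype=np.float32)
        if self.config.input_transform == "log":
            return -np.log(np.maximum(x, 0) + np.float32(1e-3))
        return x

    def n_parameters(self) -> int:
        return sum(net.n_parameters() for net in self.scales)

    # ------------------------------------------------------------ forward
    def _forward_scales(self, x: np.ndarray, train: bool,
                        targets: np.ndarray | None = None):
        """Run the pyramid; returns (stitched prob map, loss, grads applied).

        ``x``: (B, N, N, 1) normalized frames.  When ``targets`` is given,
        per-scale BCE losses are formed in patch space and backpropagated.
        """
        batch = x.shape[0]
        cond = None          # previous scale's stitched probability map
        total_loss = 0.0
        probs = None
        for s, net in enumerate(self.scales):
            tiles = tile_frames(x, s)
            if cond is not None:
                cond_tiles = tile_frames(cond, s)
                tiles = np.concatenate([tiles, cond_tiles], axis=-1)
            logits = net.forward(tiles, train=train)
            if targets is not None:
                t_tiles = tile_frames(targets, s)
                loss, dlogits = bce_with_logits(logits, t_tiles)
                net.backward(dlogits)
                total_loss += loss
            p_tiles = sigmoid(logits)
            probs = stitch_tiles(p_tiles, s, batch)
            cond = probs
        return probs, total_loss


def build_model(config: DetectorConfig | None = None) -> DetectorModel:
    """Instantiate the detector with deterministic seeded weights."""
    return DetectorModel(config or DetectorConfig())


def _check_pairs(images: np.ndarray, masks: np.ndarray,
                 config: DetectorConfig) -> None:
    if images.ndim != 3 or images.shape != masks.shape:
        raise ValueError("expected matching (n, height, width) image and mask"
                         " stacks")
    if images.shape[0] < 1:
        raise ValueError("need at least one training pair")
    if images.shape[1] != config.matrix or images.shape[2] != config.matrix:
        raise ValueError(
            f"frames are {images.shape[1]}x{images.shape[2]} but the model "
            f"matrix is {config.matrix}")
    vals = np.unique(masks)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("masks must be binary (0/1)")


def train(model: DetectorModel, images: np.ndarray, masks: np.ndarray,
          config: DetectorConfig | None = None) -> list[float]:
    """Minimize mean BCE with mini-batch Adam; early-stop on the training
    loss plateau.  Returns the per-epoch loss trace (also stored on the
    model).  Deterministic for fixed seeds.
    """
    config = config or model.config
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    _check_pairs(images, masks, config)
    masks = masks.astype(np.float32)

    images = model._transform(images)
    model.norm_offset = float(images.mean())
    rng = np.random.default_rng([config.seed, 9999])
    opt = Adam([l for net in model.scales for l in net.layers()], lr=config.lr)

    n = images.shape[0]
    crop = config.crop_size
    trace: list[float] = []
    best = np.inf
    bad = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = images[idx] - model.norm_offset
            yb = masks[idx]
            if crop is not None and crop < config.matrix:
                xb, yb = _random_crops(xb, yb, crop, rng,
                                       config.crop_positive_frac)
            xb = xb[..., None]
            yb = yb[..., None]
            _, loss = model._forward_scales(xb, train=True, targets=yb)
            opt.step()
            epoch_losses.append(loss)
        epoch_loss = float(np.mean(epoch_losses))
        trace.append(epoch_loss)
        if epoch_loss < best - config.min_delta:
            best = epoch_loss
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    model.loss_trace = trace
    return trace


def _random_crops(xb: np.ndarray, yb: np.ndarray, crop: int,
                  rng: np.random.Generator, positive_frac: float = 0.5):
    """Random square crops; a fraction is centered on mask pixels.

    Obstruction pixels are a sub-percent minority of a frame, so uniform
    crops rarely contain positives and plain BCE collapses to the trivial
    background solution; centering part of the crops on the (jittered)
    obstruction restores a usable positive rate without altering the loss.
    """
    b, h, w = xb.shape[:3]
    xi = rng.integers(0, h - crop + 1, size=b)
    yi = rng.integers(0, w - crop + 1, size=b)
    centered = rng.random(b) < positive_frac
    xc = np.empty((b, crop, crop), dtype=xb.dtype)
    yc = np.empty((b, crop, crop), dtype=yb.dtype)
    for k in range(b):
        if centered[k]:
            pos = np.argwhere(yb[k] > 0)
            if len(pos):
                pi, pj = pos[rng.integers(len(pos))]
                ji, jj = rng.integers(-crop // 4, crop // 4 + 1, size=2)
                xi[k] = np.clip(pi + ji - crop // 2, 0, h - crop)
                yi[k] = np.clip(pj + jj - crop // 2, 0, w - crop)
        xc[k] = xb[k, xi[k]:xi[k] + crop, yi[k]:yi[k] + crop]
        yc[k] = yb[k, xi[k]:xi[k] + crop, yi[k]:yi[k] + crop]
    return xc, yc


def predict(model: DetectorModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel obstruction probability map for one normalized frame."""
    return predict_batch(model, np.asarray(image)[None])[0]


def predict_batch(model: DetectorModel, images: np.ndarray,
                  chunk: int = 16) -> np.ndarray:
    """Deterministic forward pass over a stack of normalized frames."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3 or images.shape[1] != model.config.matrix \
            or images.shape[2] != model.config.matrix:
        raise ValueError(
            f"expected (n, {model.config.matrix}, {model.config.matrix}) "
            f"input, got {images.shape}")
    images = model._transform(images)
    out = np.empty_like(images)
    for start in range(0, len(images), chunk):
        xb = images[start:start + chunk] - model.norm_offset
        probs, _ = model._forward_scales(xb[..., None], train=False)
        out[start:start + chunk] = probs[..., 0]
    return out


# ---------------------------------------------------------------- persistence

def save_checkpoint(model: DetectorModel, path) -> None:
    """Single-file checkpoint: config JSON + all weights + norm state."""
    arrays = {}
    for s, net in enumerate(model.scales):
        for li, layer in enumerate(net.layers()):
            for k, v in layer.params.items():
                arrays[f"s{s}_l{li}_{k}"] = v
    arrays["norm_offset"] = np.float64(model.norm_offset)
    arrays["loss_trace"] = np.asarray(model.loss_trace, dtype=np.float64)
    cfg = asdict(model.config)
    cfg["features"] = list(cfg["features"])
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> DetectorModel:
    data = np.load(path)
    cfg = json.loads(bytes(data["config_json"]).decode())
    cfg["features"] = tuple(cfg["features"])
    if cfg.get("crop_size") is not None:
        cfg["crop_size"] = int(cfg["crop_size"])
    model = DetectorModel(DetectorConfig(**cfg))
    for s, net in enumerate(model.scales):
        for li, layer in enumerate(net.layers()):
            for k in layer.params:
                layer.params[k] = data[f"s{s}_l{li}_{k}"].copy()
    model.norm_offset = float(data["norm_offset"])
    model.loss_trace = list(data["loss_trace"])
    return model
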
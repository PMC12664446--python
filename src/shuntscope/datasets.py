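"""Deterministic dataset/fixture generation for tests, demos and training.

Writes radiograph/mask pairs in plain interchange formats: 16-bit
multi-page TIFF for count frames, 8-bit TIFF for masks, a CSV manifest
(one row per frame) and a JSON side-car with the generating parameters.
Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .materials import AttenuationTable
from .phantom import MaterialVolume, PhantomSpec, build_valve_phantom
from .projector import FrameSimulator, ProjectionGeometry
from .scene import OBSTRUCTION_VOLUME_RANGE

__all__ = ["FixtureSpec", "fixture_phantom_spec", "make_micro_dataset",
           "load_dataset", "PHANTOM_PRESETS"]


def fixture_phantom_spec() -> PhantomSpec:
    """Coarse phantom for fast tests: 0.1 mm voxels, thicker spring wire.

    Preserves the production topology (shell, spring, two balls, single
    connected cavity) at roughly 1/8 of the voxel count.
    """
    return PhantomSpec(voxel_size=0.1, spring_wire_diameter=0.35,
                       spring_pitch=1.2, spring_coils=4.0)


PHANTOM_PRESETS = {
    "default": PhantomSpec,
    "fixture": fixture_phantom_spec,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated radiograph dataset."""

    phantom: str = "fixture"
    n_obstructed: int = 10
    n_clean: int = 10
    n0: int = 400
    concentration: float = 2.0
    volume_range: tuple[float, float] = OBSTRUCTION_VOLUME_RANGE
    matrix: int = 64
    n_angles: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obstructed < 0 or self.n_clean < 0:
            raise ValueError("frame counts must be non-negative")
        if self.phantom not in PHANTOM_PRESETS:
            raise ValueError(f"unknown phantom preset {self.phantom!r}")

    def geometry(self) -> ProjectionGeometry:
        # scale the pitch so the magnified valve keeps filling ~90% of the frame
        pitch = 1.0 * 128 / self.matrix
        return ProjectionGeometry(pitch_mm=pitch, rows=self.matrix,
                                  cols=self.matrix)


def make_micro_dataset(spec: FixtureSpec, out_dir: str | Path,
                       volume: MaterialVolume | None = None) -> pd.DataFrame:
    """Generate and write a small labeled dataset; returns the manifest.

    Frame order is all obstructed frames first, then all clean frames.
    Obstructed frames carry exactly one deposition with volume uniform
    over ``spec.volume_range``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if volume is None:
        volume = build_valve_phantom(PHANTOM_PRESETS[spec.phantom]())
    sim = FrameSimulator(volume, AttenuationTable(), spec.geometry(),
                         n_angles=spec.n_angles)
    rng = np.random.default_rng([spec.seed, 77])

    frames, masks, rows = [], [], []
    lo, hi = spec.volume_range
    for i in range(spec.n_obstructed + spec.n_clean):
        obstructed = i < spec.n_obstructed
        target = float(rng.uniform(lo, hi)) if obstructed else None
        rad, mask, scene = sim.render(rng, spec.n0, spec.concentration,
                                      target, frame_index=i)
        frames.append(rad.counts.astype(np.uint16))
        masks.append(mask.mask.astype(np.uint8))
        rows.append({
            "frame": i,
            "obstructed": int(obstructed),
            "pose_angle_deg": rad.pose_angle_deg,
            "n0": rad.n0,
            "concentration": spec.concentration,
            "obstruction_volume_mm3": scene.obstruction_volume_mm3,
            "mask_pixels": int(mask.mask.sum()),
        })

    tifffile.imwrite(out / "frames.tif", np.stack(frames))
    tifffile.imwrite(out / "masks.tif", np.stack(masks))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    meta = asdict(spec)
    meta["volume_range"] = list(meta["volume_range"])
    meta["geometry"] = asdict(spec.geometry())
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return manifest


def load_dataset(path: str | Path):
    """Read a dataset written by :func:`make_micro_dataset`.

    Returns (frames uint16 stack, masks uint8 stack, manifest, meta dict).
    """
    path = Path(path)
    frames = tifffile.imread(path / "frames.tif")
    masks = tifffile.imread(path / "masks.tif")
    manifest = pd.read_csv(path / "manifest.csv")
    meta = json.loads((path / "meta.json").read_text())
    if frames.ndim == 2:
        frames = frames[None]
        masks = masks[None]
    return frames, masks, manifest, meta
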
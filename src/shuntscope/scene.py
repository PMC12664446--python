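"""Simulation scenes: contrast-filled valve with water-density obstructions.

A :class:`Scene` is a material volume whose fluid cavity is virtually
filled with Gd contrast agent, except for optional "organic deposition"
voxels assumed at water density.  Obstructions are connected blobs of a
controlled volume, grown anisotropically from a uniformly drawn cavity
seed voxel.  A bolus series emulates contrast wash-in/wash-out as a
kinematic front moving along the valve's long axis.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .materials import CAVITY, AttenuationTable
from .phantom import MaterialVolume, cavity_mask

__all__ = ["Scene", "place_obstruction", "make_scene", "bolus_series",
           "sample_obstruction_volume", "scene_mu_volume", "save_scene",
           "load_scene", "OBSTRUCTION_VOLUME_RANGE", "OBSTRUCTION_LABEL"]

# extra label id used only in serialized scenes (not a phantom material)
OBSTRUCTION_LABEL = 6

# the simulated deposition volumes span this range (mm^3), drawn uniformly
OBSTRUCTION_VOLUME_RANGE = (0.025, 0.9)


@dataclass
class Scene:
    """Material volume plus contrast/obstruction partition of the cavity.

    ``obstruction`` is a boolean grid (subset of the cavity); every other
    cavity voxel is contrast-filled, unless ``filled`` restricts the
    contrast region (bolus frames).  ``pose_angle`` is the rotation about
    the valve's long axis used when this scene is projected; ``None`` means
    "draw at projection time".
    """

    base: MaterialVolume
    obstruction: np.ndarray
    concentration: float
    obstruction_volume_mm3: float
    pose_angle: float | None = None
    seed: int | None = None
    filled: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def contrast_mask(self) -> np.ndarray:
        """Voxels attenuating as contrast agent."""
        cav = cavity_mask(self.base)
        m = cav & ~self.obstruction
        if self.filled is not None:
            m &= self.filled
        return m


def sample_obstruction_volume(rng: np.random.Generator,
                              volume_range: tuple[float, float] = OBSTRUCTION_VOLUME_RANGE,
                              ) -> float:
    """Draw a deposition volume (mm^3), uniform over ``volume_range``."""
    lo, hi = volume_range
    if not 0 < lo <= hi:
        raise ValueError("invalid obstruction volume range")
    return float(rng.uniform(lo, hi))


def place_obstruction(volume: MaterialVolume, target_volume_mm3: float,
                      seed: int | np.random.Generator,
                      max_retries: int = 20,
                      return_indices: bool = False) -> np.ndarray:
    """Grow one connected quasi-ellipsoidal blob of the target volume.

    The blob center is drawn uniformly over cavity voxels; growth is
    best-first over an anisotropic distance (random per-axis scales in
    [0.5, 2]), constrained to 6-connected cavity voxels, so the result is
    always connected and matches ``target_volume_mm3`` to within one voxel.
    """
    rng = np.random.default_rng(seed)
    vox = volume.voxel_size
    cav = cavity_mask(volume)
    # index list of cavity voxels is expensive to rebuild per frame; cache
    # it on the volume (underscore keys are never serialized)
    cav_idx = volume.metadata.get("_cavity_indices")
    if cav_idx is None:
        cav_idx = np.argwhere(cav)
        volume.metadata["_cavity_indices"] = cav_idx
    n_cavity = len(cav_idx)
    if target_volume_mm3 <= 0:
        raise ValueError("target volume must be positive")
    if target_volume_mm3 > n_cavity * vox ** 3:
        raise ValueError(
            f"target volume {target_volume_mm3} mm^3 exceeds cavity volume "
            f"{n_cavity * vox ** 3:.3f} mm^3")
    n_target = max(1, int(round(target_volume_mm3 / vox ** 3)))
    for _ in range(max_retries):
        center = cav_idx[rng.integers(len(cav_idx))]
        scales = rng.uniform(0.5, 2.0, size=3)
        grown = _grow_blob(cav, center, scales, n_target)
        if grown is not None:
            region, voxels = grown
            if return_indices:
                return region, voxels
            return region
    raise RuntimeError(
        f"could not place an obstruction of {target_volume_mm3} mm^3 after "
        f"{max_retries} attempts (cavity too fragmented near drawn centers)")


def _grow_blob(cav: np.ndarray, center: np.ndarray, scales: np.ndarray,
               n_target: int):
    """Best-first 6-connected growth ordered by anisotropic distance.

    Returns (region grid, (n, 3) voxel index array) or None if the cavity
    cannot host ``n_target`` voxels reachable from the center.
    """
    shape = cav.shape
    region = np.zeros(shape, dtype=bool)
    seen = np.zeros(shape, dtype=bool)
    c = tuple(int(v) for v in center)
    heap = [(0.0, c)]
    seen[c] = True
    voxels = []
    inv2 = 1.0 / scales ** 2
    while heap and len(voxels) < n_target:
        _, v = heapq.heappop(heap)
        region[v] = True
        voxels.append(v)
        for ax in range(3):
            for dv in (-1, 1):
                w = list(v)
                w[ax] += dv
                if not 0 <= w[ax] < shape[ax]:
                    continue
                w = tuple(w)
                if seen[w] or not cav[w]:
                    continue
                seen[w] = True
                d = ((w[0] - c[0]) ** 2 * inv2[0]
                     + (w[1] - c[1]) ** 2 * inv2[1]
                     + (w[2] - c[2]) ** 2 * inv2[2])
                heapq.heappush(heap, (float(d), w))
    if len(voxels) != n_target:
        return None
    return region, np.asarray(voxels, dtype=np.intp)


def make_scene(volume: MaterialVolume, concentration: float,
               target_volume_mm3: float | None = None,
               pose_angle: float | None = None,
               seed: int | np.random.Generator = 0) -> Scene:
    """Fill the cavity with contrast and optionally insert one obstruction.

    ``target_volume_mm3 = None`` yields the obstruction-free control scene.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if pose_angle is not None and not 0 <= pose_angle < 360:
        raise ValueError("pose_angle must lie in [0, 360)")
    meta = {}
    if target_volume_mm3 is None:
        obstruction = np.zeros(volume.shape, dtype=bool)
        vol = 0.0
    else:
        obstruction, voxels = place_obstruction(volume, target_volume_mm3,
                                                seed, return_indices=True)
        vol = float(len(voxels)) * volume.voxel_size ** 3
        meta["obstruction_voxel_indices"] = voxels
    return Scene(base=volume, obstruction=obstruction,
                 concentration=float(concentration),
                 obstruction_volume_mm3=vol, pose_angle=pose_angle,
                 seed=seed if isinstance(seed, int) else None,
                 metadata=meta)


def bolus_series(volume: MaterialVolume, concentration: float, n_frames: int,
                 fill_profile, seed: int = 0) -> list[Scene]:
    """Kinematic contrast bolus: a fill front moving along the long axis.

    ``fill_profile`` maps frame index -> filled fraction in [0, 1].  Frame 0
    is always the contrast-free baseline.  The contrast front advances (or
    recedes) along the long axis; fraction 1 fills the whole cavity.
    """
    if n_frames < 2:
        raise ValueError("a bolus series needs at least 2 frames")
    cav = cavity_mask(volume)
    ax_coord = volume.world_coords(volume.long_axis)
    idx_along = np.nonzero(cav.any(axis=tuple(a for a in range(3) if a != volume.long_axis)))[0]
    x_lo, x_hi = ax_coord[idx_along[0]], ax_coord[idx_along[-1]]
    coord_grid = ax_coord.reshape([-1 if a == volume.long_axis else 1 for a in range(3)])

    frames = []
    for k in range(n_frames):
        f = float(fill_profile(k)) if callable(fill_profile) else float(fill_profile[k])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fill fraction {f} at frame {k} outside [0, 1]")
        if k == 0:
            f = 0.0
        if f >= 1.0:
            filled = cav.copy()
        else:
            filled = cav & (coord_grid < x_lo + f * (x_hi - x_lo))
        frames.append(Scene(
            base=volume, obstruction=np.zeros(volume.shape, dtype=bool),
            concentration=float(concentration), obstruction_volume_mm3=0.0,
            pose_angle=None, seed=seed, filled=filled,
            metadata={"frame_index": k, "fill_fraction": f}))
    return frames


def save_scene(scene: Scene, path) -> None:
    """Serialize a scene as a labeled NIfTI plus a JSON side-car.

    Obstruction voxels are written with the extra label
    :data:`OBSTRUCTION_LABEL`; the side-car records concentration,
    obstruction volume, pose and seed.
    """
    import copy
    import json
    from pathlib import Path

    from .phantom import save_material_volume

    labeled = copy.copy(scene.base)
    labels = scene.base.labels.copy()
    labels[scene.obstruction] = OBSTRUCTION_LABEL
    labeled.labels = labels
    labeled.material_table = {**scene.base.material_table,
                              OBSTRUCTION_LABEL: "obstruction"}
    save_material_volume(labeled, path)
    side = {
        "concentration": scene.concentration,
        "obstruction_volume_mm3": scene.obstruction_volume_mm3,
        "pose_angle": scene.pose_angle,
        "seed": scene.seed,
    }
    path = Path(path)
    base = Path(str(path.with_suffix("").with_suffix("")))
    Path(str(base) + ".scene.json").write_text(json.dumps(side, indent=2))


def load_scene(path) -> Scene:
    import json
    from pathlib import Path

    from .phantom import load_material_volume

    volume = load_material_volume(path)
    obstruction = volume.labels == OBSTRUCTION_LABEL
    volume.labels = np.where(obstruction, CAVITY, volume.labels).astype(np.uint8)
    volume.material_table.pop(OBSTRUCTION_LABEL, None)
    path = Path(path)
    base = Path(str(path.with_suffix("").with_suffix("")))
    side = json.loads(Path(str(base) + ".scene.json").read_text())
    return Scene(base=volume, obstruction=obstruction,
                 concentration=side["concentration"],
                 obstruction_volume_mm3=side["obstruction_volume_mm3"],
                 pose_angle=side["pose_angle"], seed=side["seed"])


def scene_mu_volume(scene: Scene, attenuation: AttenuationTable) -> np.ndarray:
    """Voxelwise linear attenuation (1/cm) of a scene, float32."""
    labels = scene.base.labels
    mu = np.zeros(labels.shape, dtype=np.float32)
    for label in np.unique(labels):
        if label == CAVITY:
            continue
        mu[labels == label] = attenuation.mu_for_label(int(label))
    cav = cavity_mask(scene.base)
    mu[cav] = attenuation.mu_water  # un-filled cavity holds water
    mu[scene.contrast_mask()] = attenuation.mu_contrast(scene.concentration)
    # obstructions are water-density; explicit for clarity even though the
    # cavity default already set them
    mu[scene.obstruction] = attenuation.mu_water
    return mu
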
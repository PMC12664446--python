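"""Cone-beam forward projection with Beer-Lambert attenuation and
binomial photon-counting statistics.

Geometry: point source at the lab origin, beam along +z.  The valve sits
with its long axis along lab x, centered at distance SOD from the source;
the detector plane is at SDD.  Pose rotation is about the valve's long
axis (the clinically relevant degree of freedom).

Per detector pixel, the optical depth is the line integral of the linear
attenuation coefficient along the source-pixel ray, evaluated by trilinear
sampling of the voxelized mu map at a step of half a voxel.  Detected
counts are Binomial(N0, exp(-tau)) per pixel, independent across pixels.
The ground-truth obstruction mask is projected with exact ray/voxel-box
intersections on the same rays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .materials import AttenuationTable
from .phantom import MaterialVolume, cavity_mask
from .scene import Scene, make_scene, scene_mu_volume

__all__ = ["ProjectionGeometry", "Radiograph", "ObstructionMask",
           "path_integrals", "transmission", "sample_counts", "project_mask",
           "render_frame", "FrameSimulator"]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Cone-beam acquisition geometry.

    Defaults follow the demonstrated bench geometry (SOD 5.5 cm,
    SDD 35 cm) with a 128x128 detector whose pitch is chosen so the
    magnified valve fills ~90% of the frame.
    """

    sod_cm: float = 5.5
    sdd_cm: float = 35.0
    pitch_mm: float = 1.0
    rows: int = 128
    cols: int = 128
    pose_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.sod_cm < self.sdd_cm:
            raise ValueError("need 0 < SOD < SDD")
        if self.pitch_mm <= 0 or self.rows < 1 or self.cols < 1:
            raise ValueError("invalid detector specification")

    @property
    def magnification(self) -> float:
        return self.sdd_cm / self.sod_cm

    @classmethod
    def ml_default(cls, pose_angle_deg: float = 0.0) -> "ProjectionGeometry":
        """128x128 frame for the learning pipeline."""
        return cls(pose_angle_deg=pose_angle_deg)

    @classmethod
    def physical(cls, pose_angle_deg: float = 0.0) -> "ProjectionGeometry":
        """The photon-counting bench detector: 2048x512 pixels at 75 um."""
        return cls(pitch_mm=0.075, rows=2048, cols=512,
                   pose_angle_deg=pose_angle_deg)


@dataclass
class Radiograph:
    """2D count image with its open-beam normalization and geometry."""

    counts: np.ndarray
    n0: int
    geometry: ProjectionGeometry
    frame_index: int = 0
    pose_angle_deg: float = 0.0


@dataclass
class ObstructionMask:
    """Binary ground-truth projection of the obstruction voxels."""

    mask: np.ndarray


# ------------------------------------------------------------------ rays

def _pixel_dirs(geometry: ProjectionGeometry) -> np.ndarray:
    """Unit ray directions source->pixel, shape (rows, cols, 3), lab frame."""
    u = (np.arange(geometry.rows) - (geometry.rows - 1) / 2) * geometry.pitch_mm
    v = (np.arange(geometry.cols) - (geometry.cols - 1) / 2) * geometry.pitch_mm
    sdd = geometry.sdd_cm * 10.0
    d = np.empty((geometry.rows, geometry.cols, 3), dtype=np.float64)
    d[..., 0] = u[:, None]
    d[..., 1] = v[None, :]
    d[..., 2] = sdd
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    return d


def _lab_to_volume(volume: MaterialVolume, pose_angle_deg: float):
    """Rotation (lab->volume) and offsets mapping lab mm to voxel indices.

    A lab point q maps to volume world coords via
    ``w = R_x(-theta) @ (q - (0, 0, SOD)) + c_v`` with c_v the volume
    center; voxel indices are ``(w - origin) / voxel_size``.
    """
    th = np.deg2rad(pose_angle_deg)
    c, s = np.cos(th), np.sin(th)
    # R_x(-theta) acting on (x, y, z_rel)
    rot = np.array([[1, 0, 0], [0, c, s], [0, -s, c]])
    center = volume.origin + volume.voxel_size * (np.array(volume.shape) - 1) / 2
    return rot, center


class _RaySampler:
    """Shared ray grid for line integrals of several volumes at one pose.

    Clips every ray to the bounding cylinder/slab of the volume (the
    cylinder axis is the rotation axis, so the clip is pose-invariant) and
    lays out samples at a fixed step with half-step offset.
    """

    def __init__(self, volume: MaterialVolume, geometry: ProjectionGeometry,
                 step_mm: float | None = None,
                 pixel_sel: np.ndarray | None = None):
        if step_mm is None:
            step_mm = volume.voxel_size / 2
        if step_mm > volume.voxel_size:
            raise ValueError(
                f"ray sampling step {step_mm} mm exceeds the voxel size "
                f"{volume.voxel_size} mm; integrals would be unreliable")
        self.step_mm = step_mm
        self.geometry = geometry
        self.shape = (geometry.rows, geometry.cols)

        dirs = _pixel_dirs(geometry)
        sod = geometry.sod_cm * 10.0
        ext = volume.voxel_size * np.array(volume.shape)
        x_half = ext[0] / 2 + volume.voxel_size
        r_cyl = np.hypot(ext[1], ext[2]) / 2 + volume.voxel_size

        d = dirs.reshape(-1, 3)
        if pixel_sel is not None:
            flat_sel = pixel_sel.reshape(-1)
            d = d[flat_sel]
        # ray-cylinder intersection in the (y, z) plane, center (0, SOD)
        a = d[:, 1] ** 2 + d[:, 2] ** 2
        b = -2 * sod * d[:, 2]
        cc = sod ** 2 - r_cyl ** 2
        disc = b ** 2 - 4 * a * cc
        hit = disc > 0
        sq = np.sqrt(np.maximum(disc, 0.0))
        t0 = (-b - sq) / (2 * a)
        t1 = (-b + sq) / (2 * a)
        # clip to the axial slab |x| <= x_half
        with np.errstate(divide="ignore", invalid="ignore"):
            tx0 = np.where(d[:, 0] != 0, -x_half / d[:, 0], -np.inf)
            tx1 = np.where(d[:, 0] != 0, x_half / d[:, 0], np.inf)
        lo = np.minimum(tx0, tx1)
        hi = np.maximum(tx0, tx1)
        t0 = np.maximum(t0, lo)
        t1 = np.minimum(t1, hi)
        hit &= t1 > t0

        self._dirs = d[hit]
        self._t0 = t0[hit]
        n = int(np.ceil((t1 - t0)[hit].max() / step_mm)) if np.any(hit) else 0
        self._n_samples = n

        idx = np.arange(geometry.rows * geometry.cols)
        if pixel_sel is not None:
            idx = idx[flat_sel]
        self._flat_idx = idx[hit]

        self._vox = volume.voxel_size
        self._origin = volume.origin
        self._rot, self._center = _lab_to_volume(volume, geometry.pose_angle_deg)

    def _coords(self) -> np.ndarray:
        rot, center = self._rot, self._center
        t = self._t0[:, None] + (np.arange(self._n_samples) + 0.5) * self.step_mm
        pts = self._dirs[:, None, :] * t[:, :, None]      # lab, (P, n, 3)
        pts[:, :, 2] -= self.geometry.sod_cm * 10.0
        pts = pts @ rot.T
        pts += center
        return ((pts - self._origin) / self._vox).astype(np.float32)

    def integrate(self, mu_volume: np.ndarray) -> np.ndarray:
        """Line integral (value * cm) of a voxel field over every ray."""
        out = np.zeros(self.shape, dtype=np.float32).reshape(-1)
        if self._n_samples == 0 or len(self._dirs) == 0:
            return out.reshape(self.shape)
        coords = self._coords()
        vals = ndimage.map_coordinates(
            np.asarray(mu_volume, dtype=np.float32), coords.reshape(-1, 3).T,
            order=1, mode="constant", cval=0.0, prefilter=False)
        out[self._flat_idx] = vals.reshape(len(self._dirs), -1).sum(axis=1) \
            * (self.step_mm / 10.0)
        return out.reshape(self.shape)

    def integrate_pair(self, vol_a: np.ndarray, vol_b: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Two line integrals sharing one coordinate evaluation."""
        out_a = np.zeros(self.shape, dtype=np.float32).reshape(-1)
        out_b = np.zeros(self.shape, dtype=np.float32).reshape(-1)
        if self._n_samples == 0 or len(self._dirs) == 0:
            return out_a.reshape(self.shape), out_b.reshape(self.shape)
        coords = self._coords()
        packed = np.asarray(vol_a, dtype=np.complex64).copy()
        packed += 1j * np.asarray(vol_b, dtype=np.float32)
        vals = ndimage.map_coordinates(
            packed, coords.reshape(-1, 3).T, order=1,
            mode="constant", cval=0.0, prefilter=False)
        sums = vals.reshape(len(self._dirs), -1).sum(axis=1) * (self.step_mm / 10.0)
        out_a[self._flat_idx] = sums.real
        out_b[self._flat_idx] = sums.imag
        return out_a.reshape(self.shape), out_b.reshape(self.shape)


# ------------------------------------------------------------------ ops

def path_integrals(scene: Scene, attenuation: AttenuationTable,
                   geometry: ProjectionGeometry,
                   step_mm: float | None = None) -> np.ndarray:
    """Optical depth tau per detector pixel (dimensionless, mu in 1/cm)."""
    mu = scene_mu_volume(scene, attenuation)
    pose = scene.pose_angle if scene.pose_angle is not None \
        else geometry.pose_angle_deg
    geom = replace(geometry, pose_angle_deg=pose)
    sampler = _RaySampler(scene.base, geom, step_mm)
    return sampler.integrate(mu)


def transmission(tau: np.ndarray) -> np.ndarray:
    """Beer-Lambert survival probability p = exp(-tau)."""
    tau = np.asarray(tau)
    if np.any(tau < 0):
        raise ValueError("optical depth must be non-negative")
    return np.exp(-tau)


def sample_counts(p: np.ndarray, n0: int,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Per-pixel counts ~ Binomial(N0, p), independent across pixels."""
    p = np.asarray(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("survival probabilities must lie in [0, 1]")
    if int(n0) < 1:
        raise ValueError("open-beam counts must be a positive integer")
    rng = np.random.default_rng(seed)
    return rng.binomial(int(n0), p)


def _ray_box_lengths(o: np.ndarray, d: np.ndarray, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    """Intersection lengths of rays (P,3 dir, common origin) with boxes (K,3)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo[None, :, :] - o[None, None, :]) / d[:, None, :]
        t_hi = (hi[None, :, :] - o[None, None, :]) / d[:, None, :]
    t_min = np.nanmax(np.minimum(t_lo, t_hi), axis=2)
    t_max = np.nanmin(np.maximum(t_lo, t_hi), axis=2)
    return np.maximum(t_max - t_min, 0.0)


def project_mask(scene: Scene, geometry: ProjectionGeometry) -> ObstructionMask:
    """Pixel true iff its source-pixel ray intersects an obstruction voxel.

    Uses exact ray/axis-aligned-box intersections against the individual
    obstruction voxels, on the same rays as :func:`path_integrals`.
    """
    pose = scene.pose_angle if scene.pose_angle is not None \
        else geometry.pose_angle_deg
    geom = replace(geometry, pose_angle_deg=pose)
    mask = np.zeros((geom.rows, geom.cols), dtype=bool)
    vox_idx = scene.metadata.get("obstruction_voxel_indices")
    if vox_idx is None:
        vox_idx = np.argwhere(scene.obstruction)
    if len(vox_idx) == 0:
        return ObstructionMask(mask)

    volume = scene.base
    rot, center = _lab_to_volume(volume, pose)
    # transform rays into the volume frame (common origin = source)
    sod = geom.sod_cm * 10.0
    o_vol = rot @ np.array([0.0, 0.0, -sod]) + center
    dirs = _pixel_dirs(geom).reshape(-1, 3) @ rot.T

    vox = volume.voxel_size
    centers = volume.origin + vox_idx * vox
    lo_all = centers - vox / 2
    hi_all = centers + vox / 2

    # shortlist pixels by the inflated bounding box of the whole obstruction
    bb_lo = lo_all.min(axis=0)[None, :]
    bb_hi = hi_all.max(axis=0)[None, :]
    cand = _ray_box_lengths(o_vol, dirs, bb_lo, bb_hi)[:, 0] > 0
    if not np.any(cand):
        return ObstructionMask(mask)

    d_sel = dirs[cand]
    hit = np.zeros(len(d_sel), dtype=bool)
    chunk = max(1, int(2e6) // max(len(d_sel), 1))
    for k0 in range(0, len(vox_idx), chunk):
        lengths = _ray_box_lengths(o_vol, d_sel, lo_all[k0:k0 + chunk],
                                   hi_all[k0:k0 + chunk])
        hit |= (lengths > 0).any(axis=1)
    flat = np.nonzero(cand)[0][hit]
    mask.reshape(-1)[flat] = True
    return ObstructionMask(mask)


def render_frame(scene: Scene, attenuation: AttenuationTable,
                 geometry: ProjectionGeometry, n0: int,
                 seed: int | np.random.Generator = 0,
                 step_mm: float | None = None,
                 frame_index: int = 0) -> tuple[Radiograph, ObstructionMask]:
    """Full forward model: tau -> transmission -> binomial counts + mask.

    If the scene has no fixed pose, the pose angle is drawn uniformly on
    [0, 360) from the seeded generator.
    """
    rng = np.random.default_rng(seed)
    pose = scene.pose_angle
    if pose is None:
        pose = float(rng.uniform(0.0, 360.0))
        scene = Scene(base=scene.base, obstruction=scene.obstruction,
                      concentration=scene.concentration,
                      obstruction_volume_mm3=scene.obstruction_volume_mm3,
                      pose_angle=pose, seed=scene.seed, filled=scene.filled,
                      metadata=scene.metadata)
    tau = path_integrals(scene, attenuation, geometry, step_mm)
    counts = sample_counts(transmission(tau), n0, rng)
    mask = project_mask(scene, geometry)
    radiograph = Radiograph(counts=counts, n0=int(n0), geometry=geometry,
                            frame_index=frame_index, pose_angle_deg=pose)
    return radiograph, mask


# ------------------------------------------------------------ fast path

class FrameSimulator:
    """Generates radiograph/mask pairs quickly via a static-projection bank.

    The static part of the optical depth (shell, spring, balls, water-filled
    cavity) and the cavity path-length map depend only on the pose angle, so
    they are cached on a discrete angle grid:

        tau(theta, c) = tau_base(theta) + k_gd * c * L_cavity(theta)

    and a placed obstruction only subtracts its contrast deficit,

        delta_tau = -k_gd * c * L_obstruction,

    evaluated on the same rays/sample grid restricted to the obstruction's
    footprint.  Pose angles are drawn uniformly from the angle grid
    (default 1-degree spacing), which stands in for the continuous uniform
    pose of the direct :func:`render_frame` path.
    """

    def __init__(self, volume: MaterialVolume, attenuation: AttenuationTable,
                 geometry: ProjectionGeometry | None = None,
                 n_angles: int = 360, step_mm: float | None = None):
        self.volume = volume
        self.attenuation = attenuation
        self.geometry = geometry or ProjectionGeometry.ml_default()
        self.n_angles = int(n_angles)
        self.step_mm = step_mm if step_mm is not None else volume.voxel_size / 2
        self._bank: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._mu_base: np.ndarray | None = None
        self._cav_ind: np.ndarray | None = None

    def angle_deg(self, angle_index: int) -> float:
        return 360.0 * angle_index / self.n_angles

    def _static_maps(self, angle_index: int) -> tuple[np.ndarray, np.ndarray]:
        if angle_index not in self._bank:
            if self._mu_base is None:
                baseline = make_water_scene(self.volume)
                self._mu_base = scene_mu_volume(baseline, self.attenuation)
                self._cav_ind = cavity_mask(self.volume).astype(np.float32)
            geom = replace(self.geometry,
                           pose_angle_deg=self.angle_deg(angle_index))
            sampler = _RaySampler(self.volume, geom, self.step_mm)
            tau_base, l_cav = sampler.integrate_pair(self._mu_base,
                                                     self._cav_ind)
            self._bank[angle_index] = (tau_base, l_cav)
        return self._bank[angle_index]

    def tau_frame(self, concentration: float, angle_index: int,
                  obstruction: np.ndarray | None = None,
                  obstruction_indices: np.ndarray | None = None) -> np.ndarray:
        """Optical depth of a (possibly obstructed) fully-filled scene."""
        tau_base, l_cav = self._static_maps(angle_index)
        k = self.attenuation.k_gd
        tau = tau_base + k * concentration * l_cav
        if obstruction is not None and np.any(obstruction):
            geom = replace(self.geometry,
                           pose_angle_deg=self.angle_deg(angle_index))
            if obstruction_indices is None:
                obstruction_indices = np.argwhere(obstruction)
            sel = self._footprint(obstruction_indices, geom)
            if np.any(sel):
                sampler = _RaySampler(self.volume, geom, self.step_mm,
                                      pixel_sel=sel)
                l_obs = sampler.integrate(obstruction.astype(np.float32))
                tau = tau - k * concentration * l_obs
        return tau

    def _footprint(self, obstruction_indices: np.ndarray,
                   geom: ProjectionGeometry) -> np.ndarray:
        """Pixels whose rays cross the inflated obstruction bounding box."""
        rot, center = _lab_to_volume(self.volume, geom.pose_angle_deg)
        sod = geom.sod_cm * 10.0
        o_vol = rot @ np.array([0.0, 0.0, -sod]) + center
        dirs = _pixel_dirs(geom).reshape(-1, 3) @ rot.T
        idx = obstruction_indices
        vox = self.volume.voxel_size
        lo = (self.volume.origin + idx.min(axis=0) * vox - 1.5 * vox)[None, :]
        hi = (self.volume.origin + idx.max(axis=0) * vox + 1.5 * vox)[None, :]
        lengths = _ray_box_lengths(o_vol, dirs, lo, hi)[:, 0]
        return (lengths > 0).reshape(geom.rows, geom.cols)

    def render(self, rng: np.random.Generator, n0: int, concentration: float,
               target_volume_mm3: float | None = None,
               angle_index: int | None = None,
               frame_index: int = 0) -> tuple[Radiograph, ObstructionMask, Scene]:
        """Draw pose/obstruction, cast the frame, and sample counts."""
        if angle_index is None:
            angle_index = int(rng.integers(self.n_angles))
        pose = self.angle_deg(angle_index)
        scene = make_scene(self.volume, concentration, target_volume_mm3,
                           pose_angle=pose, seed=rng)
        tau = self.tau_frame(
            concentration, angle_index,
            scene.obstruction if target_volume_mm3 is not None else None,
            scene.metadata.get("obstruction_voxel_indices"))
        counts = sample_counts(transmission(tau), n0, rng)
        geom = replace(self.geometry, pose_angle_deg=pose)
        mask = project_mask(scene, geom)
        radiograph = Radiograph(counts=counts, n0=int(n0), geometry=geom,
                                frame_index=frame_index, pose_angle_deg=pose)
        return radiograph, mask, scene


def make_water_scene(volume: MaterialVolume) -> Scene:
    """Baseline scene: cavity filled with water (concentration 0)."""
    return Scene(base=volume, obstruction=np.zeros(volume.shape, dtype=bool),
                 concentration=0.0, obstruction_volume_mm3=0.0, pose_angle=0.0)
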
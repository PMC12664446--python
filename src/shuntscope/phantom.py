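"""Parametric voxel phantom of a gravitational ball-in-cone CSF shunt valve.

The phantom reproduces the radiographically relevant topology of a
gravitational shunt valve: a metal shell with a conical inlet section, an
inlet spring, a ruby ball resting above the cone seat, a tantalum ball
acting as the gravitational unit, and a single connected fluid cavity that
opens to the outside only through the inlet and outlet channels.

Geometry is built analytically (cones, spheres, a helical tube) and
rasterized onto an isotropic voxel grid.  The long axis of the valve is
grid axis 0; world coordinates are measured in mm at voxel centers, with
``x = 0`` at the inlet face and the valve axis at ``y = z = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .materials import (BACKGROUND, CAVITY, MATERIAL_NAMES, RUBY_BALL, SHELL,
                        SPRING, TANTALUM_BALL)

__all__ = ["PhantomSpec", "MaterialVolume", "build_valve_phantom",
           "cavity_mask", "save_material_volume", "load_material_volume"]


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of the parametric valve, all lengths in mm.

    The defaults give an ~18 mm x 6 mm valve envelope with a spring wire of
    0.25 mm, resolved by the default 0.05 mm voxels.
    """

    length: float = 18.0
    outer_diameter: float = 6.0
    shell_thickness: float = 0.5
    cone_length: float = 5.0
    inlet_radius: float = 0.5
    outlet_radius: float = 0.5
    spring_start: float = 5.5
    spring_coils: float = 5.0
    spring_pitch: float = 1.0
    spring_wire_diameter: float = 0.25
    spring_helix_radius: float = 1.8
    ruby_ball_diameter: float = 1.5
    ruby_ball_center: float = 1.8
    tantalum_ball_diameter: float = 2.0
    tantalum_ball_center: float = 14.0
    voxel_size: float = 0.05
    margin_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = [self.length, self.outer_diameter, self.shell_thickness,
                   self.cone_length, self.inlet_radius, self.outlet_radius,
                   self.spring_pitch, self.spring_wire_diameter,
                   self.spring_helix_radius, self.ruby_ball_diameter,
                   self.tantalum_ball_diameter, self.voxel_size]
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom dimensions must be strictly positive")
        smallest = min(self.spring_wire_diameter, self.shell_thickness,
                       2 * self.inlet_radius, 2 * self.outlet_radius)
        if self.voxel_size > smallest / 3:
            raise ValueError(
                f"voxel_size {self.voxel_size} mm is too coarse to resolve the "
                f"smallest feature ({smallest} mm, e.g. the spring wire); need "
                f"voxel_size <= {smallest / 3:.4g} mm")
        if self.cone_length >= self.length:
            raise ValueError("cone_length must be smaller than valve length")


@dataclass
class MaterialVolume:
    """3D grid of material labels with isotropic voxel size.

    Attributes
    ----------
    labels : (nx, ny, nz) uint8 array
        Material id per voxel (see :mod:`shuntscope.materials`).
    voxel_size : float
        Isotropic voxel edge, mm.
    origin : (3,) array
        World coordinate (mm) of the center of voxel (0, 0, 0).
    material_table : dict
        Material id -> name.
    long_axis : int
        Grid axis of the valve's long axis (always 0 for built phantoms).
    metadata : dict
        Cavity bookkeeping and the generating spec.
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray
    material_table: dict[int, str] = field(default_factory=lambda: dict(MATERIAL_NAMES))
    long_axis: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates (mm) along a grid axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def cavity_volume_mm3(self) -> float:
        return float(np.count_nonzero(self.labels == CAVITY)) * self.voxel_size ** 3


def cavity_mask(volume: MaterialVolume) -> np.ndarray:
    """Binary grid that is true exactly where the label is cavity."""
    return volume.labels == CAVITY


def _helix_mask(spec: PhantomSpec, x: np.ndarray, y: np.ndarray,
                z: np.ndarray) -> np.ndarray:
    """Rasterize the inlet spring as a tube around a helical center line."""
    a = spec.spring_helix_radius
    wire_r = spec.spring_wire_diameter / 2
    t_max = 2 * np.pi * spec.spring_coils
    dpitch = spec.spring_pitch / (2 * np.pi)
    # arc-length step <= voxel/2 keeps the distance error below half a voxel
    speed = np.hypot(a, dpitch)
    n_pts = int(np.ceil(t_max * speed / (spec.voxel_size / 2))) + 1
    t = np.linspace(0.0, t_max, n_pts)
    curve = np.stack([spec.spring_start + dpitch * t,
                      a * np.cos(t), a * np.sin(t)], axis=1)

    r = np.sqrt(y ** 2 + z ** 2)
    pad = wire_r + spec.voxel_size
    candidates = ((x >= spec.spring_start - pad)
                  & (x <= spec.spring_start + spec.spring_pitch * spec.spring_coils + pad)
                  & (np.abs(r - a) <= pad))
    idx = np.nonzero(candidates)
    pts = np.stack([x[idx], y[idx], z[idx]], axis=1)
    mask = np.zeros(x.shape, dtype=bool)
    if pts.size:
        dist, _ = cKDTree(curve).query(pts, workers=-1)
        sel = dist <= wire_r
        mask[idx[0][sel], idx[1][sel], idx[2][sel]] = True
    return mask


def build_valve_phantom(spec: PhantomSpec | None = None) -> MaterialVolume:
    """Rasterize the parametric valve onto a labeled voxel grid.

    The construction is fully deterministic for a fixed spec.  The returned
    volume satisfies: one label per voxel; the cavity is a single
    6-connected component; the cavity touches background only through the
    inlet/outlet channels.  Cavity volume (mm^3) is reported in metadata.
    """
    spec = spec or PhantomSpec()
    vox = spec.voxel_size
    m = spec.margin_voxels

    nx = int(np.ceil(spec.length / vox)) + 2 * m
    half = spec.outer_diameter / 2
    nt = int(np.ceil(spec.outer_diameter / vox)) + 2 * m
    if nt % 2 == 0:
        nt += 1  # odd transverse extent keeps the axis on a voxel center

    origin = np.array([(0.5 - m) * vox, -(nt - 1) / 2 * vox, -(nt - 1) / 2 * vox])
    xs = origin[0] + vox * np.arange(nx)
    ys = origin[1] + vox * np.arange(nt)
    x, y, z = np.meshgrid(xs, ys, ys, indexing="ij", sparse=False)
    r = np.sqrt(y ** 2 + z ** 2)

    t = spec.shell_thickness
    R_out_max = half
    R_in_max = half - t
    # interior radius profile: cone from inlet_radius to R_in_max, then cylinder
    cone_slope = (R_in_max - spec.inlet_radius) / spec.cone_length
    R_in = np.where(x < spec.cone_length,
                    spec.inlet_radius + cone_slope * x, R_in_max)
    R_out = np.minimum(R_in + t, R_out_max)

    inside_axial = (x >= 0) & (x <= spec.length)
    outer = inside_axial & (r <= R_out)
    interior = ((x >= t) & (x <= spec.length - t) & (r < R_in))
    interior |= inside_axial & (x < t) & (r < spec.inlet_radius)
    interior |= inside_axial & (x > spec.length - t) & (r < spec.outlet_radius)

    labels = np.zeros((nx, nt, nt), dtype=np.uint8)
    labels[outer & ~interior] = SHELL

    spring = _helix_mask(spec, x, y, z) & interior
    ruby = (x - spec.ruby_ball_center) ** 2 + y ** 2 + z ** 2 \
        <= (spec.ruby_ball_diameter / 2) ** 2
    tantalum = (x - spec.tantalum_ball_center) ** 2 + y ** 2 + z ** 2 \
        <= (spec.tantalum_ball_diameter / 2) ** 2
    labels[interior] = CAVITY
    labels[spring] = SPRING
    labels[ruby & interior] = RUBY_BALL
    labels[tantalum & interior] = TANTALUM_BALL

    cavity = labels == CAVITY
    n_comp = ndimage.label(cavity, structure=ndimage.generate_binary_structure(3, 1))[1]
    if n_comp != 1:
        raise RuntimeError(
            f"phantom cavity split into {n_comp} components; adjust the spec "
            "(a ball or the spring is sealing the fluid path)")

    n_cavity = int(np.count_nonzero(cavity))
    volume = MaterialVolume(
        labels=labels, voxel_size=vox, origin=origin,
        metadata={
            "cavity_voxels": n_cavity,
            "cavity_volume_mm3": n_cavity * vox ** 3,
            "spec": asdict(spec),
        })
    return volume


# --------------------------------------------------------------------- io

def save_material_volume(volume: MaterialVolume, path: str | Path) -> None:
    """Write labels as integer NIfTI plus a JSON side-car with metadata."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), affine)
    nib.save(img, path)
    sidecar = {
        "voxel_size": volume.voxel_size,
        "origin": list(map(float, volume.origin)),
        "long_axis": volume.long_axis,
        "material_table": {str(k): v for k, v in volume.material_table.items()},
        "metadata": {k: v for k, v in volume.metadata.items()
                     if not k.startswith("_")},
    }
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
    Path(str(sidecar_path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_material_volume(path: str | Path) -> MaterialVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.uint8)
    sidecar_path = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar_path.read_text())
    return MaterialVolume(
        labels=labels,
        voxel_size=float(meta["voxel_size"]),
        origin=np.asarray(meta["origin"], dtype=float),
        material_table={int(k): v for k, v in meta["material_table"].items()},
        long_axis=int(meta["long_axis"]),
        metadata=meta["metadata"],
    )
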
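"""Linear attenuation coefficients for the valve materials.

The forward model is monochromatic at a single effective energy (default
60 keV, a reasonable effective energy for a filtered 90 kVp tube spectrum).
Each material is assigned a linear attenuation coefficient mu in 1/cm; the
contrast-filled cavity attenuates as water plus a term linear in the Gd
concentration,

    mu(c) = mu_water + k_gd * c      [1/cm, c in mmol/ml]

with k_gd the Gd contrast slope.  All values live in a plain table that can
be round-tripped through YAML, so the physics can be refined (different
effective energy, different alloys) without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# canonical material ids used by the phantom / scene modules
BACKGROUND = 0
SHELL = 1
SPRING = 2
RUBY_BALL = 3
TANTALUM_BALL = 4
CAVITY = 5

MATERIAL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    SHELL: "shell",
    SPRING: "spring",
    RUBY_BALL: "ruby_ball",
    TANTALUM_BALL: "tantalum_ball",
    CAVITY: "cavity",
}

# Approximate monochromatic values at 60 keV, from standard photon
# cross-section tabulations (mass attenuation coefficient times density):
#   water  0.206 1/cm
#   Ti shell      ~0.31 cm^2/g * 4.51 g/cm^3  ~ 1.42 1/cm
#   steel spring  ~1.20 cm^2/g * 7.87 g/cm^3  ~ 9.5  1/cm
#   ruby (Al2O3)  ~0.24 cm^2/g * 3.98 g/cm^3  ~ 0.94 1/cm
#   tantalum      ~4.5  cm^2/g * 16.65 g/cm^3 ~ 75   1/cm (just below K-edge)
#   Gd slope: 4.0 cm^2/g * 0.15725 g/ml per mmol/ml ~ 0.63 1/cm per mmol/ml
_DEFAULT_MU = {
    "background": 0.0,
    "shell": 1.42,
    "spring": 9.5,
    "ruby_ball": 0.94,
    "tantalum_ball": 75.0,
    "water": 0.206,
}
_DEFAULT_K_GD = 0.63


@dataclass(frozen=True)
class AttenuationTable:
    """Material -> linear attenuation coefficient map at one effective energy.

    Parameters
    ----------
    mu : dict
        Map from material name to mu in 1/cm.  Must contain at least the
        names in :data:`MATERIAL_NAMES` (with ``cavity`` replaced by
        ``water``) -- the cavity's mu is derived from ``water`` via
        :meth:`mu_contrast`.
    k_gd : float
        Contrast slope, 1/cm per (mmol/ml) of Gd.
    energy_kev : float
        Effective photon energy the coefficients refer to (metadata only).
    """

    mu: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MU))
    k_gd: float = _DEFAULT_K_GD
    energy_kev: float = 60.0

    def __post_init__(self) -> None:
        missing = {"background", "shell", "spring", "ruby_ball",
                   "tantalum_ball", "water"} - set(self.mu)
        if missing:
            raise ValueError(f"attenuation table missing materials: {sorted(missing)}")
        if any(v < 0 for v in self.mu.values()):
            raise ValueError("attenuation coefficients must be non-negative")
        if self.k_gd < 0:
            raise ValueError("k_gd must be non-negative")

    def mu_contrast(self, concentration: float) -> float:
        """mu of the contrast-filled cavity at ``concentration`` mmol/ml."""
        if concentration < 0:
            raise ValueError("concentration must be non-negative")
        return self.mu["water"] + self.k_gd * concentration

    @property
    def mu_water(self) -> float:
        return self.mu["water"]

    def mu_for_label(self, label: int, concentration: float = 0.0) -> float:
        """mu for a phantom material id; cavity voxels use the contrast mu."""
        if label == CAVITY:
            return self.mu_contrast(concentration)
        return self.mu[MATERIAL_NAMES[label]]

    # ------------------------------------------------------------------ io
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AttenuationTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(mu=data["mu"], k_gd=float(data["k_gd"]),
                   energy_kev=float(data.get("energy_kev", 60.0)))
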
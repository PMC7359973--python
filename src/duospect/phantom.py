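"""Digital dual-isotope liver phantom.

The phantom emulates the clinical scene of a 166Ho radioembolization
procedure imaged together with 99mTc-colloid: an ellipsoidal body containing
a liver with one or more hot tumors, two lungs, 166Ho-microsphere activity
distributed over the liver with a tumor-to-normal concentration ratio (plus
an optional small lung shunt), and 99mTc-colloid activity confined to the
healthy liver (Kupffer-cell uptake — colloid is absent in tumor tissue).

Attenuation maps are organ-wise constants at the two photopeak energies
(81 keV for 166Ho, 140 keV for 99mTc) and densities follow the dosimetry
convention of 1.06 g/ml for soft tissue and 0.3 g/ml for lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .geometry import RigidTransform, move_volume, warn_if_support_clipped
from .volume import VoxelVolume

__all__ = [
    "Organ",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "true_dose_map",
    "apply_rigid_motion",
    "LABELS",
]

# organ label codes, painted in this order (later labels overwrite earlier)
LABELS = {"air": 0, "body": 1, "lung": 4, "liver": 2, "tumor": 3}


@dataclass(frozen=True)
class Organ:
    """A labeled ellipsoid; center is relative to the grid center, in mm."""

    name: str  # one of "body", "liver", "tumor", "lung"
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def contains(self, pts_rel_center: np.ndarray) -> np.ndarray:
        r = np.asarray(self.radii_mm, dtype=float)
        if np.any(r <= 0):
            return np.zeros(pts_rel_center.shape[:-1], dtype=bool)
        d = (pts_rel_center - np.asarray(self.center_mm)) / r
        return (d**2).sum(axis=-1) <= 1.0


def default_organs() -> list[Organ]:
    """Body, liver, one 33-ml tumor, two lungs — all ellipsoids, in mm
    relative to the grid center of the default 64x64x48 @ 4.8 mm grid."""
    return [
        Organ("body", (0.0, 0.0, 0.0), (140.0, 115.0, 106.0)),
        Organ("lung", (-45.0, 0.0, 58.0), (38.0, 48.0, 45.0)),
        Organ("lung", (45.0, 0.0, 58.0), (38.0, 48.0, 45.0)),
        Organ("liver", (-40.0, 10.0, -45.0), (75.0, 55.0, 48.0)),
        Organ("tumor", (-10.0, 10.0, -35.0), (20.0, 20.0, 20.0)),
    ]


@dataclass
class PhantomSpec:
    """Everything needed to voxelize a phantom.

    Activities are the totals present at scan time: the clinical protocol
    scans at ~250 MBq of 166Ho with an additional 50 MBq of 99mTc-colloid
    (the adopted 5:1 Ho:Tc ratio).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (4.8, 4.8, 4.8)
    organs: list[Organ] = field(default_factory=default_organs)
    ho_total_activity_mbq: float = 250.0
    tc_total_activity_mbq: float = 50.0
    tumor_to_normal_uptake_ratio: float = 4.0
    lung_shunt_fraction: float = 0.02
    seed: int = 0
    # organ-wise attenuation (1/cm) at the two photopeak energies; lungs are
    # 0.3x soft tissue, air 0
    mu_soft_81: float = 0.18
    mu_soft_140: float = 0.15
    lung_mu_scale: float = 0.3
    liver_density_g_ml: float = 1.06
    lung_density_g_ml: float = 0.3

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.ho_total_activity_mbq < 0 or self.tc_total_activity_mbq < 0:
            raise ValueError("activities must be non-negative")
        if self.tumor_to_normal_uptake_ratio <= 0:
            raise ValueError("tumor_to_normal_uptake_ratio must be > 0")
        if not 0 <= self.lung_shunt_fraction < 1:
            raise ValueError("lung_shunt_fraction must be in [0, 1)")
        half = (np.asarray(self.grid_shape) - 1) / 2 * np.asarray(self.spacing)
        for org in self.organs:
            c = np.abs(np.asarray(org.center_mm))
            if np.any(c + np.asarray(org.radii_mm) > half + np.asarray(self.spacing)):
                raise ValueError(f"organ {org.name} extends outside the grid")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str) -> None:
        d = {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "organs": [
                {"name": o.name, "center_mm": list(o.center_mm), "radii_mm": list(o.radii_mm)}
                for o in self.organs
            ],
            "ho_total_activity_mbq": self.ho_total_activity_mbq,
            "tc_total_activity_mbq": self.tc_total_activity_mbq,
            "tumor_to_normal_uptake_ratio": self.tumor_to_normal_uptake_ratio,
            "lung_shunt_fraction": self.lung_shunt_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        organs = [
            Organ(o["name"], tuple(o["center_mm"]), tuple(o["radii_mm"]))
            for o in d.pop("organs", [])
        ] or default_organs()
        d = {k: (tuple(v) if k in ("grid_shape", "spacing") else v) for k, v in d.items()}
        return cls(organs=organs, **d)


@dataclass
class Phantom:
    """Voxelized ground truth: labels, per-isotope activity (Bq/ml),
    attenuation maps at 81 and 140 keV (1/cm), and mass density (g/ml)."""

    labels: VoxelVolume
    ho_activity: VoxelVolume
    tc_activity: VoxelVolume
    mu_81: VoxelVolume
    mu_140: VoxelVolume
    density: VoxelVolume
    spec: PhantomSpec | None = None

    def mask(self, name: str) -> np.ndarray:
        return self.labels.data == LABELS[name]

    @property
    def liver_mask(self) -> np.ndarray:
        # tumor voxels are liver voxels that were overwritten with the tumor code
        return (self.labels.data == LABELS["liver"]) | (self.labels.data == LABELS["tumor"])

    @property
    def healthy_liver_mask(self) -> np.ndarray:
        return self.labels.data == LABELS["liver"]


def _voxel_centers_rel(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape)
    sp = np.asarray(spec.spacing)
    axes = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, sp)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a :class:`PhantomSpec` into ground-truth volumes.

    Activity is piecewise constant per compartment and normalized against the
    voxelized organ volumes, so the voxel-integrated totals reproduce the
    prescribed totals to float precision. Deterministic given the spec.
    """
    spec.validate()
    pts = _voxel_centers_rel(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    for paint in ("body", "lung", "liver", "tumor"):
        for org in spec.organs:
            if org.name == paint:
                labels[org.contains(pts)] = LABELS[paint]

    tumor = labels == LABELS["tumor"]
    healthy = labels == LABELS["liver"]
    lung = labels == LABELS["lung"]
    body = labels != LABELS["air"]
    if tumor.any() and not healthy.any():
        raise ValueError("tumor present without surrounding liver")
    # geometric containment checks
    for org in spec.organs:
        if org.name == "tumor":
            inside = org.contains(pts)
            liver_union = np.zeros_like(inside)
            for lv in spec.organs:
                if lv.name == "liver":
                    liver_union |= lv.contains(pts)
            if np.any(inside & ~liver_union):
                raise ValueError("tumor is not contained in the liver")
        if org.name == "lung":
            for lv in spec.organs:
                if lv.name == "liver" and np.any(org.contains(pts) & lv.contains(pts)):
                    raise ValueError("lungs overlap the liver")

    vox_ml = float(np.prod(spec.spacing)) / 1000.0
    v_h, v_t, v_lung = (m.sum() * vox_ml for m in (healthy, tumor, lung))

    ho = np.zeros(spec.grid_shape, dtype=np.float64)
    tc = np.zeros(spec.grid_shape, dtype=np.float64)
    ho_bq = spec.ho_total_activity_mbq * 1e6
    tc_bq = spec.tc_total_activity_mbq * 1e6
    if ho_bq > 0 and (v_h + v_t) > 0:
        shunt = spec.lung_shunt_fraction if v_lung > 0 else 0.0
        liver_bq = ho_bq * (1 - shunt)
        a_normal = liver_bq / (v_h + spec.tumor_to_normal_uptake_ratio * v_t)
        ho[healthy] = a_normal
        ho[tumor] = spec.tumor_to_normal_uptake_ratio * a_normal
        if shunt > 0:
            ho[lung] = ho_bq * shunt / v_lung
    if tc_bq > 0 and v_h > 0:
        tc[healthy] = tc_bq / v_h  # colloid: healthy liver only, never tumor

    mu81 = np.zeros(spec.grid_shape)
    mu140 = np.zeros(spec.grid_shape)
    for m, soft in ((mu81, spec.mu_soft_81), (mu140, spec.mu_soft_140)):
        m[body] = soft
        m[lung] = spec.lung_mu_scale * soft
    density = np.ones(spec.grid_shape)  # unit density outside body (unused by VOIs)
    density[body] = spec.liver_density_g_ml
    density[lung] = spec.lung_density_g_ml

    sp, og = spec.spacing, (0.0, 0.0, 0.0)
    vol = lambda d: VoxelVolume(d, sp, og)  # noqa: E731
    return Phantom(
        labels=vol(labels),
        ho_activity=vol(ho),
        tc_activity=vol(tc),
        mu_81=vol(mu81),
        mu_140=vol(mu140),
        density=vol(density),
        spec=spec,
    )


def true_dose_map(phantom: Phantom, administered_activity_mbq: float) -> VoxelVolume:
    """Ground-truth absorbed dose (Gy) from the noiseless 166Ho activity,
    rescaled so the total matches the administered activity. This is the
    recovery target the reconstruction pipeline is judged against."""
    from .dosimetry import DoseModel, dose_map, rescale_to_administered

    if administered_activity_mbq < 0:
        raise ValueError("administered activity must be non-negative")
    if administered_activity_mbq == 0 or phantom.ho_activity.integrate() == 0:
        return phantom.ho_activity.copy(data=np.zeros(phantom.ho_activity.shape))
    act = rescale_to_administered(phantom.ho_activity, administered_activity_mbq)
    return dose_map(act, phantom.density, DoseModel())


def apply_rigid_motion(phantom: Phantom, t: RigidTransform) -> Phantom:
    """Move every phantom volume consistently by ``t`` (trilinear for
    continuous volumes, nearest-neighbor for labels). Identity returns a
    voxel-identical copy; support pushed outside the grid raises a warning."""
    if t.is_identity():
        return Phantom(
            labels=phantom.labels.copy(),
            ho_activity=phantom.ho_activity.copy(),
            tc_activity=phantom.tc_activity.copy(),
            mu_81=phantom.mu_81.copy(),
            mu_140=phantom.mu_140.copy(),
            density=phantom.density.copy(),
            spec=phantom.spec,
        )
    moved_labels = move_volume(phantom.labels, t, interpolation="nearest")
    warn_if_support_clipped(phantom.labels.data > 0, moved_labels.data > 0)
    moved = {
        name: move_volume(getattr(phantom, name), t, interpolation="linear")
        for name in ("ho_activity", "tc_activity", "mu_81", "mu_140", "density")
    }
    return Phantom(labels=moved_labels, spec=phantom.spec, **moved)


def with_activities(
    phantom: Phantom, ho_scale: float = 1.0, tc_scale: float = 1.0
) -> Phantom:
    """Copy with per-isotope activity scaled (e.g. tc_scale=0 for the
    Ho-only acquisition arm)."""
    return Phantom(
        labels=phantom.labels,
        ho_activity=phantom.ho_activity.copy(data=phantom.ho_activity.data * ho_scale),
        tc_activity=phantom.tc_activity.copy(data=phantom.tc_activity.data * tc_scale),
        mu_81=phantom.mu_81,
        mu_140=phantom.mu_140,
        density=phantom.density,
        spec=phantom.spec,
    )
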
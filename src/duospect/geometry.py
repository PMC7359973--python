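"""Rigid transforms and volume resampling.

A :class:`RigidTransform` is parameterized by a translation in mm and three
Euler angles in degrees. Rotations are applied about the volume center in
x -> y -> z order (extrinsic), so the world map of a transform ``T`` is

    y = R_z R_y R_x (x - c) + c + t

with ``c`` the grid center in mm. ``apply_rigid_motion``-style operations
move a volume *by* ``T`` (``moved(v) = orig(T^-1 v)``), while
:func:`resample_into` applies ``T`` as the lookup map and therefore *undoes*
a motion of ``T`` — registration returns the motion it estimated and the
caller resamples with it directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import VoxelVolume

__all__ = ["RigidTransform", "resample_into"]


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid transform: translation (mm) + Euler rotation (deg)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    def is_identity(self, atol: float = 0.0) -> bool:
        return all(abs(v) <= atol for v in self.translation) and all(
            abs(v) <= atol for v in self.rotation_deg
        )

    @property
    def rotation_matrix(self) -> np.ndarray:
        # extrinsic x->y->z order: R = Rz @ Ry @ Rx
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def map_points(self, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Apply the world map to points of shape (..., 3)."""
        R = self.rotation_matrix
        return (pts - center) @ R.T + center + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        t = np.asarray(self.translation)
        rot_inv = Rotation.from_matrix(R.T).as_euler("xyz", degrees=True)
        return RigidTransform(
            translation=tuple(-(R.T @ t)), rotation_deg=tuple(rot_inv)
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first), same center convention."""
        Ra, ta = self.rotation_matrix, np.asarray(self.translation)
        Rb, tb = other.rotation_matrix, np.asarray(other.translation)
        R = Ra @ Rb
        t = Ra @ tb + ta
        ang = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        return RigidTransform(translation=tuple(t), rotation_deg=tuple(ang))

    def as_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation),
            "rotation_deg": list(self.rotation_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            translation=tuple(d.get("translation_mm", (0, 0, 0))),
            rotation_deg=tuple(d.get("rotation_deg", (0, 0, 0))),
        )


def _index_affine(vol: VoxelVolume, world_map_linear: np.ndarray, world_map_offset: np.ndarray):
    """Convert a world-coordinate lookup map ``w -> A w + b`` to index space."""
    S = np.diag(vol.spacing)
    Sinv = np.diag([1.0 / s for s in vol.spacing])
    og = np.asarray(vol.origin)
    A_idx = Sinv @ world_map_linear @ S
    b_idx = Sinv @ (world_map_linear @ og + world_map_offset - og)
    return A_idx, b_idx


def resample_into(
    moving: VoxelVolume,
    transform: RigidTransform,
    interpolation: str = "linear",
    fixed_grid: VoxelVolume | None = None,
) -> VoxelVolume:
    """Resample ``moving`` onto ``fixed_grid`` using ``transform`` as lookup map.

    ``out(v) = moving(T(v))`` — this undoes a prior motion of ``T`` applied to
    the moving volume. Labels should use ``interpolation='nearest'``,
    continuous volumes ``'linear'``.
    """
    grid = fixed_grid if fixed_grid is not None else moving
    if fixed_grid is not None and not np.allclose(grid.spacing, moving.spacing):
        raise ValueError("fixed and moving grids must share spacing")
    if transform.is_identity():
        return VoxelVolume(moving.data.copy(), grid.spacing, grid.origin)
    order = {"nearest": 0, "linear": 1}[interpolation]
    c = grid.center_mm
    R = transform.rotation_matrix
    t = np.asarray(transform.translation)
    # world lookup: y = R (v - c) + c + t  =  R v + (c + t - R c)
    A_idx, b_idx = _index_affine(moving, R, c + t - R @ c)
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=np.float64),
        A_idx,
        offset=b_idx,
        output_shape=grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    if np.issubdtype(moving.data.dtype, np.integer):
        out = out.round().astype(moving.data.dtype)
    return VoxelVolume(out, grid.spacing, grid.origin)


def move_volume(
    vol: VoxelVolume, transform: RigidTransform, interpolation: str = "linear"
) -> VoxelVolume:
    """Move a volume *by* ``transform`` (``moved(v) = vol(T^-1 v)``)."""
    if transform.is_identity():
        return vol.copy()
    return resample_into(vol, transform.inverse(), interpolation=interpolation)


def warn_if_support_clipped(before: np.ndarray, after: np.ndarray) -> None:
    lost = float(before.sum()) - float(after.sum())
    if before.sum() > 0 and lost / float(before.sum()) > 0.001:
        warnings.warn(
            "rigid motion moved part of the support outside the grid "
            f"({100 * lost / float(before.sum()):.2f}% lost)",
            stacklevel=3,
        )
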
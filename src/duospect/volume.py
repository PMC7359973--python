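"""Voxel volume container.

A :class:`VoxelVolume` is a 3D scalar field on a regular grid. Depending on
context the values are activity concentration (Bq/ml), linear attenuation
(1/cm), mass density (g/ml), absorbed dose (Gy) or integer organ labels.

Coordinate convention (used everywhere in the package): voxel indices are
0-based and world coordinates in mm are ``index * spacing + origin``, i.e.
the origin is the world position of voxel (0, 0, 0)'s center. Axis order is
(x, y, z) with z the patient's long (scanner rotation) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D scalar field with grid spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing : tuple of float
        Voxel size in mm along each axis; all entries must be positive.
    origin : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinates of the grid center (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self, data: np.ndarray | None = None) -> "VoxelVolume":
        """Copy, optionally replacing the data array (grid is kept)."""
        return VoxelVolume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            origin=self.origin,
        )

    # -- integrals ------------------------------------------------------
    def integrate(self) -> float:
        """Sum of values times voxel volume.

        For a concentration field in Bq/ml this is the total activity in Bq.
        """
        return float(self.data.sum(dtype=np.float64) * self.voxel_volume_ml)

    # -- IO -------------------------------------------------------------
    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        data = np.asarray(self.data)
        if data.dtype == np.int64:  # NIfTI-1 has no 64-bit integer type
            data = data.astype(np.int32)
        if data.dtype == bool:
            data = data.astype(np.uint8)
        img = nib.Nifti1Image(data, affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelVolume":
        img = nib.load(path)
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in affine[:3, 3])
        return cls(data=np.asanyarray(img.dataobj), spacing=spacing, origin=origin)
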
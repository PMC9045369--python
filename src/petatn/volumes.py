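"""Core imaging container: a 3D brain volume with its voxel-to-world geometry.

All stages of the pipeline exchange :class:`BrainVolume` objects.  World
coordinates are millimetres in RAS orientation; voxel indices are 0-based and
axial slices run along the third voxel axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class UnsupportedAffineError(ValueError):
    """Raised when an operation requires an axis-aligned scaling affine."""


@dataclasses.dataclass
class BrainVolume:
    """A 3D real-valued intensity grid with voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units for raw PET, dimensionless for SUVR).
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (mm, RAS). Must be invertible.
    space : str
        ``"native"`` or ``"template"``.
    modality : str
        ``"PBB3"``, ``"PIB"`` or ``"FDG"``.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = "template"
    modality: str = "PBB3"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def require_axis_aligned(self) -> np.ndarray:
        """Return per-axis scales, or raise if the affine has shear/rotation."""
        rot = self.affine[:3, :3]
        scales = np.linalg.norm(rot, axis=0)
        if not np.allclose(rot, np.diag(np.sign(np.diag(rot)) * scales), atol=1e-6):
            raise UnsupportedAffineError(
                "only axis-aligned scaling affines are supported for this operation"
            )
        return scales

    def with_data(self, data: np.ndarray) -> "BrainVolume":
        return BrainVolume(data, self.affine.copy(), self.space, self.modality)

    def same_grid(self, other: "BrainVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    # -- NIfTI I/O ---------------------------------------------------------

    def to_nifti(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header["descrip"] = f"{self.modality}|{self.space}".encode()[:80]
        path = Path(path)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(
        cls, path: str | Path, space: str = "template", modality: str = "PBB3"
    ) -> "BrainVolume":
        img = nib.load(str(path))
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
        if "|" in descrip:
            modality, space = descrip.split("|")[:2]
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, space, modality)


# -- rigid transforms ------------------------------------------------------


def rigid_matrix(translation_mm, rotation_deg, center_mm) -> np.ndarray:
    """4x4 world-space rigid map: rotate (x,y,z order, degrees) about
    ``center_mm``, then translate."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    M = np.eye(4)
    M[:3, :3] = R
    center = np.asarray(center_mm, dtype=float)
    M[:3, 3] = np.asarray(translation_mm, dtype=float) + center - R @ center
    return M


def world_center(volume: BrainVolume) -> np.ndarray:
    """World coordinates of the grid centre."""
    half = (np.asarray(volume.shape, dtype=float) - 1) / 2.0
    return (volume.affine @ np.append(half, 1.0))[:3]


def resample_rigid(
    moving: BrainVolume,
    fixed: BrainVolume,
    translation_mm=(0.0, 0.0, 0.0),
    rotation_deg=(0.0, 0.0, 0.0),
    order: int = 1,
) -> BrainVolume:
    """Resample ``moving`` onto ``fixed``'s grid under a world-space rigid map.

    The transform carries moving-space world points to fixed-space world
    points; each fixed voxel is filled by pulling from the inverse-mapped
    location in ``moving``. Linear interpolation, zero fill outside.
    """
    M = rigid_matrix(translation_mm, rotation_deg, world_center(fixed))
    # fixed voxel -> fixed world -> inverse rigid -> moving world -> moving voxel
    full = np.linalg.inv(moving.affine) @ np.linalg.inv(M) @ fixed.affine
    out = ndimage.affine_transform(
        moving.data,
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=fixed.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return BrainVolume(out, fixed.affine.copy(), fixed.space, moving.modality)
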
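"""In-memory containers for CT-like volumes and binary masks.

Axis convention
---------------
Arrays are indexed ``data[i, j, k]`` with axes mapped to the world RAS
frame: ``i`` runs along +x (patient right), ``j`` along +y (anterior),
``k`` along +z (superior).  World coordinates in millimetres are
``origin + index * spacing`` — the affine is diagonal; oblique
acquisitions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError

__all__ = ["Volume", "Mask", "dice"]


@dataclass
class Volume:
    """A 3D scalar image in Hounsfield units with voxel geometry.

    Parameters
    ----------
    data:
        3D float array of intensities (HU).
    spacing:
        Voxel edge lengths in mm along (x, y, z); strictly positive.
    origin:
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    meta:
        Free-form provenance dictionary (thresholds, source files, ...).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"volume data must be 3D, got {self.data.ndim}D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.origin.shape != (3,):
            raise GeometryError(f"origin must be a 3-vector, got {self.origin}")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 RAS affine (diagonal spacing, origin translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_diagonal(self) -> float:
        """Length in mm of one voxel's space diagonal."""
        return float(np.linalg.norm(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def same_geometry(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            spacing=spacing,
            origin=aff[:3, 3].copy(),
            meta={"source": str(path)},
        )

    @classmethod
    def from_dicom_series(cls, directory: str | Path) -> "Volume":
        """Read an axial DICOM series as one volume.

        Slices are sorted by the stacking (z) component of
        ImagePositionPatient; rescale slope/intercept are applied so the
        payload is in HU.  Assumes an axis-aligned acquisition.
        """
        import pydicom

        files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
        datasets = [pydicom.dcmread(str(f)) for f in files if f.is_file()]
        datasets = [d for d in datasets if hasattr(d, "ImagePositionPatient")]
        if not datasets:
            raise GeometryError(f"no DICOM slices with ImagePositionPatient in {directory}")
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        first = datasets[0]
        row_spacing, col_spacing = (float(x) for x in first.PixelSpacing)
        zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
        dz = float(np.median(np.diff(zs))) if len(zs) > 1 else 1.0
        if dz <= 0:
            raise GeometryError("DICOM slices are not strictly increasing in z")
        slope = float(getattr(first, "RescaleSlope", 1.0))
        intercept = float(getattr(first, "RescaleIntercept", 0.0))
        # DICOM pixel arrays are (row, col) = (y, x); transpose to (x, y).
        data = np.stack([d.pixel_array.T for d in datasets], axis=2).astype(float)
        data = data * slope + intercept
        origin = np.array([float(first.ImagePositionPatient[0]),
                           float(first.ImagePositionPatient[1]), zs[0]])
        return cls(data=data, spacing=np.array([col_spacing, row_spacing, dz]),
                   origin=origin, meta={"source": str(directory), "format": "dicom"})


@dataclass
class Mask:
    """A binary grid sharing the geometry of its source :class:`Volume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"mask data must be 3D, got {self.data.ndim}D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive lengths, got {self.spacing}")

    # Geometry helpers shared with Volume
    shape = Volume.shape
    affine = Volume.affine
    voxel_diagonal = Volume.voxel_diagonal
    index_to_world = Volume.index_to_world
    world_to_index = Volume.world_to_index
    same_geometry = Volume.same_geometry

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Mask":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        return cls(
            data=np.asarray(img.get_fdata()) > 0.5,
            spacing=spacing,
            origin=aff[:3, 3].copy(),
            meta={"source": str(path)},
        )

    @classmethod
    def like(cls, ref: "Volume | Mask", data: np.ndarray, **meta) -> "Mask":
        if data.shape != ref.shape:
            raise GeometryError(f"mask shape {data.shape} != reference shape {ref.shape}")
        return cls(data=data, spacing=ref.spacing.copy(), origin=ref.origin.copy(), meta=dict(meta))


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap coefficient between two masks of identical geometry."""
    if not a.same_geometry(b):
        raise GeometryError("dice requires masks with identical geometry")
    inter = np.logical_and(a.data, b.data).sum()
    denom = a.data.sum() + b.data.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(inter) / float(denom)
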
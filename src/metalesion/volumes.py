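"""NIfTI-backed image volumes.

A cohort of co-registered brain volumes is represented one
:class:`ImageVolume` at a time: a 3D intensity grid plus the voxel->world
affine.  Volumes are read and written as NIfTI-1 through nibabel; the grid is
kept in float64 in memory and stored as float32 on disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ImageVolume", "read_volume", "write_volume"]


@dataclass
class ImageVolume:
    """A 3D intensity grid with a voxel-to-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm mapping.  Must be invertible.
    space : str
        Free-text label of the common space the volume lives in
        (e.g. ``"MNI"`` or ``"synthetic"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    space: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        rot = self.affine[:3, :3]
        sizes = np.linalg.norm(rot, axis=0)
        offdiag = rot - np.diag(np.diag(rot))
        if np.any(np.abs(offdiag) > 1e-6 * max(sizes.max(), 1.0)):
            logger.warning(
                "non-orthogonal affine: voxel sizes taken as column norms"
            )
        return sizes

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.data)))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.affine.copy(), self.space)

    @staticmethod
    def isotropic(data: np.ndarray, voxel_size_mm: float, space: str = "synthetic") -> "ImageVolume":
        """Build a volume with a diagonal affine of the given voxel size."""
        aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
        return ImageVolume(np.asarray(data, dtype=float), aff, space)


def read_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI-1 volume from disk.

    Raises
    ------
    ValueError
        If the file cannot be parsed as NIfTI or the affine is singular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed NIfTI header in {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"malformed NIfTI header in {path}: singular affine")
    if not np.all(np.isfinite(data)):
        warnings.warn(f"{path}: volume contains non-finite voxels", stacklevel=2)
    return ImageVolume(data, affine, space="file")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI-1; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path
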
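"""Reading, writing and assembling 3D diffusion-weighted volumes.

The in-memory container is :class:`DiffusionVolume`: a floating-point
intensity grid in arbitrary units (a.u.) with voxel spacing in mm and a
canonical RAS axis order (axis 0 -> right, axis 1 -> anterior, axis 2 ->
superior).  All geometry downstream of this module works in mm at voxel
centres: ``position = origin + index * spacing``.

NIfTI is the on-disk format; files are reoriented to canonical RAS on load,
so the projection's polar axis (superior) is always array axis 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .errors import VolumeFormatError


@dataclass
class GroundTruth:
    """Planted truth attached to synthetic volumes."""

    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    territory: Optional[str] = None  # None when no lesion is planted
    stroke_side: str = "left"


@dataclass
class DiffusionVolume:
    """A 3D diffusion-intensity grid with physical metadata.

    Parameters
    ----------
    data
        3D float array of diffusion intensities (a.u.).
    spacing
        Voxel spacing in mm per axis, strictly positive.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    orientation
        Axis-label triple; always "RAS" for volumes built by this package.
    ground_truth
        Optional planted masks/labels (synthetic volumes only).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: str = "RAS"
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise VolumeFormatError("volume must be a non-empty 3D grid")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise VolumeFormatError(f"voxel spacing must be > 0, got {self.spacing}")
        gt = self.ground_truth
        if gt is not None:
            for name in ("brain_mask", "lesion_mask"):
                mask = getattr(gt, name)
                if mask.shape != self.data.shape:
                    raise VolumeFormatError(f"{name} shape {mask.shape} != grid {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_positions(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Physical centres (mm) of all voxels, or of the voxels in ``mask``.

        Returns an (n, 3) array in the same order as ``np.nonzero(mask)``.
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.origin + idx * self.spacing

    def center_mm(self) -> np.ndarray:
        """Physical centre of the grid."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing


def save_volume(volume: DiffusionVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> DiffusionVolume:
    """Load a NIfTI volume, reorienting to canonical RAS.

    Raises
    ------
    VolumeFormatError
        If the file is missing, truncated, not a 3D image, or carries
        non-positive voxel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.get_fdata(), dtype=np.float32)
    except VolumeFormatError:
        raise
    except Exception as exc:  # nibabel raises several distinct types
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(~np.isfinite(zooms)) or np.any(zooms <= 0):
        raise VolumeFormatError(f"{path}: invalid voxel spacing {zooms}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return DiffusionVolume(data=data, spacing=zooms, origin=origin, orientation="RAS")


def stack_slices(
    slices: Sequence[np.ndarray],
    thickness: float,
    in_plane_spacing: tuple[float, float] = (1.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> DiffusionVolume:
    """Assemble ordered axial slices into a 3D stack.

    Through-plane spacing equals the slice ``thickness`` (mm), mirroring how
    multi-slice MR acquisitions are stacked for evaluation.
    """
    if not slices:
        raise VolumeFormatError("need at least one slice")
    if thickness <= 0:
        raise VolumeFormatError("slice thickness must be > 0")
    shapes = {np.asarray(s).shape for s in slices}
    if len(shapes) != 1 or any(len(s) != 2 for s in shapes):
        raise VolumeFormatError(f"slices must share one 2D shape, got {sorted(shapes)}")
    data = np.stack([np.asarray(s, dtype=np.float32) for s in slices], axis=2)
    spacing = np.array([in_plane_spacing[0], in_plane_spacing[1], thickness])
    return DiffusionVolume(data=data, spacing=spacing, origin=np.asarray(origin, float))
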
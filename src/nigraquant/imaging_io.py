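"""NIfTI input/output and the shared image-geometry contract.

Every array in the package is a 3D grid indexed ``(x, y, z)`` where the third
axis is the axial slice index and index 0 is the most inferior slice.  In-plane
resolution defaults to 0.35 x 0.35 mm with 3 mm slices, i.e. the neuromelanin
slab geometry the measurements assume.  All synthetic subjects share a single
grid, so geometry mismatches are treated as errors rather than resampled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "RoiMask",
    "GeometryError",
    "DialectError",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]

#: Voxel sizes closer than this (mm) are considered identical.
VOXEL_SIZE_ATOL_MM = 1e-4

MASK_LABELS = frozenset(
    {
        "snc_left",
        "snc_right",
        "background",
        "sensorimotor",
        "associative",
        "limbic",
        "consensus",
        "rater",
    }
)


class GeometryError(ValueError):
    """Two grids that must share shape and voxel size do not."""


class DialectError(ValueError):
    """A mask file carries ambiguous (non-binary) values."""


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing in mm.

    Axis 2 is the axial direction; slice 0 is the most inferior slice.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz


@dataclass
class RoiMask:
    """A binary region-of-interest grid sharing a :class:`VolumeImage` geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    label: str = "rater"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask values must be 0/1, found {vals[:8]}")
            self.data = self.data.astype(bool)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be three positive values, got {self.voxel_size_mm}")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def nonempty_slices(self) -> np.ndarray:
        """Axial indices of slices containing at least one mask voxel."""
        return np.flatnonzero(self.data.any(axis=(0, 1)))


def check_same_geometry(a, b, what: str = "grids") -> None:
    """Raise :class:`GeometryError` unless shapes and voxel sizes match."""
    if a.shape != b.shape:
        raise GeometryError(f"{what} have different shapes: {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_size_mm, b.voxel_size_mm, atol=VOXEL_SIZE_ATOL_MM, rtol=0.0):
        raise GeometryError(
            f"{what} have different voxel sizes: {a.voxel_size_mm} vs {b.voxel_size_mm}"
        )


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(image: VolumeImage, path: str | os.PathLike) -> None:
    """Write an intensity volume as float32 NIfTI-1 (.nii or .nii.gz)."""
    nii = nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm))
    nii.header.set_zooms(image.voxel_size_mm)
    nii.to_filename(str(path))


def load_volume(path: str | os.PathLike) -> VolumeImage:
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(np.float32)
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return VolumeImage(data=data, voxel_size_mm=zooms)


def save_mask(mask: RoiMask, path: str | os.PathLike) -> None:
    """Write a binary mask as uint8 0/1 NIfTI-1."""
    nii = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size_mm))
    nii.header.set_zooms(mask.voxel_size_mm)
    nii.to_filename(str(path))


def load_mask(path: str | os.PathLike, reference: VolumeImage, label: str = "rater") -> RoiMask:
    """Load a mask, verify it shares the reference geometry, and binarize it.

    Values > 0.5 become foreground.  Values falling in the ambiguous band
    (0.25, 0.75) indicate a fractional/probabilistic mask written in some other
    dialect and raise :class:`DialectError` instead of being silently rounded.
    """
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(np.float64)
    zooms = tuple(float(z) for z in nii.header.get_zooms()[:3])
    if data.shape != reference.shape:
        raise GeometryError(
            f"mask shape {data.shape} does not match reference {reference.shape}"
        )
    if not np.allclose(zooms, reference.voxel_size_mm, atol=VOXEL_SIZE_ATOL_MM, rtol=0.0):
        raise GeometryError(
            f"mask voxel size {zooms} does not match reference {reference.voxel_size_mm}"
        )
    ambiguous = (data > 0.25) & (data < 0.75)
    if np.any(ambiguous):
        raise DialectError(
            f"mask {path} has {int(ambiguous.sum())} values in (0.25, 0.75); "
            "expected a binary 0/1 mask"
        )
    return RoiMask(data=data > 0.5, voxel_size_mm=reference.voxel_size_mm, label=label)
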
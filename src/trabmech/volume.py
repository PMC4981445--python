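"""Volume containers and file I/O.

Two thin containers are used throughout the package: :class:`GrayVolume`
(scalar attenuation field) and :class:`BinaryVolume` (bone mask).  Both carry
an isotropic voxel size in millimetres; physical position of voxel ``(i,j,k)``
is ``index * voxel_mm`` (voxel-centred, 0-based).  Axis 2 (the last numpy
axis) is the "axis 3" of the mechanics convention.

MetaImage (.mhd/.raw) round-trips go through SimpleITK, NIfTI through
nibabel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np


def _check_isotropic(spacing, tol: float = 1e-6) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.max() - spacing.min() > tol * spacing.mean():
        raise ValueError(f"anisotropic voxels not supported: spacing={spacing}")
    return float(spacing.mean())


@dataclass
class GrayVolume:
    """3D scalar field with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def side_mm(self) -> tuple[float, ...]:
        return tuple(s * self.voxel_mm for s in self.data.shape)


@dataclass
class BinaryVolume:
    """Bone mask (True = bone) with isotropic voxel size (mm)."""

    data: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def bvtv(self) -> float:
        """Bone volume fraction: bone voxels / total voxels (exact ratio)."""
        return float(np.count_nonzero(self.data)) / self.data.size

    @property
    def volume_mm3(self) -> float:
        return self.data.size * self.voxel_mm**3


def crop_centered(vol, side_mm: float):
    """Centered sub-cube of physical side ``side_mm``, whole-voxel rounding.

    Center index rounds half-down so crops are reproducible.  Works on either
    container and returns the same type.
    """
    n = int(round(side_mm / vol.voxel_mm))
    shape = vol.data.shape
    if any(n > s for s in shape):
        raise ValueError(
            f"requested {side_mm} mm ({n} voxels) exceeds volume extent {shape}"
        )
    slices = []
    for s in shape:
        # half-down tie break on the centering offset
        start = int(np.ceil((s - n) / 2 - 0.5))
        slices.append(slice(start, start + n))
    out = vol.data[tuple(slices)]
    return type(vol)(out, vol.voxel_mm)


def read_volume(path: str) -> GrayVolume:
    """Read a MetaImage (.mhd) or NIfTI (.nii/.nii.gz) volume."""
    if path.endswith(".mhd") or path.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        voxel = _check_isotropic(img.GetSpacing())
        # SimpleITK arrays come back (z,y,x); transpose to (x,y,z)
        return GrayVolume(sitk.GetArrayFromImage(img).T, voxel)
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(path)
        voxel = _check_isotropic(img.header.get_zooms()[:3])
        return GrayVolume(np.asanyarray(img.dataobj), voxel)
    raise ValueError(f"unrecognized volume format: {path}")


def write_volume(vol, path: str) -> None:
    """Write a volume as MetaImage or NIfTI, inferred from the extension."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    if path.endswith(".mhd") or path.endswith(".mha"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing((vol.voxel_mm,) * 3)
        sitk.WriteImage(img, path)
        return
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag([vol.voxel_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
        return
    raise ValueError(f"unrecognized volume format: {path}")


def read_mask(path: str) -> BinaryVolume:
    vol = read_volume(path)
    return BinaryVolume(vol.data > 0, vol.voxel_mm)
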
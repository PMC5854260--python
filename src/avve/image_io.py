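"""NIfTI volume and mask I/O, world geometry, and isotropic resampling.

The working containers are :class:`VolumeImage` (3D scalar intensities plus the
voxel-index -> world-mm affine) and :class:`BinaryMask` (a boolean volume on the
same grid).  Conventions follow the NIfTI standard as exposed by nibabel:

* voxel indices are 0-based and a voxel's world position is the affine image of
  its integer index (voxel-centre convention);
* the world origin is the scanner isocenter, which is what the
  normalized-distance feature measures against;
* intensities are whatever the header scale/slope produce — no rescaling.

Resampling to an isotropic grid (the segmentation pipeline works at 1 mm) uses
linear interpolation for intensities and nearest-neighbour for masks, so masks
stay strictly binary.  The output grid spans ``ceil(extent_mm / target)`` voxels
per axis and is anchored at the original first voxel centre.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GridAlignmentError, InvalidGeometryError, UnsupportedImageError

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_dicom_series",
    "voxel_volume_mm3",
    "resample_isotropic",
    "resample_mask",
]


@dataclasses.dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar intensity grid with its voxel-to-world transform.

    Attributes
    ----------
    data:
        3D array of finite scalar intensities (arbitrary MR units).
    affine:
        Invertible 4x4 voxel-index -> world-mm transform.
    spacing:
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all positive.
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise UnsupportedImageError(
                f"expected a 3D scalar volume, got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise UnsupportedImageError("volume contains non-finite intensities")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidGeometryError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise InvalidGeometryError("affine is not invertible")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InvalidGeometryError(f"spacing must be 3 positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an ``(n, 3)`` array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A boolean volume aligned to a :class:`VolumeImage` grid."""

    data: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise UnsupportedImageError(
                f"expected a 3D mask, got shape {data.shape}"
            )
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise UnsupportedImageError(
                    f"mask values must be binary, found {uniq[:8]}"
                )
            data = data.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise InvalidGeometryError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())  # applies header scl_slope/scl_inter
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise UnsupportedImageError(
            f"{path.name}: expected a 3D scalar payload, got shape {data.shape}"
        )
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InvalidGeometryError(f"{path.name}: affine is not invertible")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, affine, spacing


def load_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) file into a :class:`VolumeImage`.

    Header scale/slope are applied by nibabel; no further intensity rescaling
    is performed.  4D or non-scalar payloads are rejected rather than sliced.
    """
    data, affine, spacing = _load_nifti(path)
    return VolumeImage(data=data, affine=affine, spacing=spacing)


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving data (dtype included), affine
    and spacing, so write -> read round trips are lossless."""
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: VolumeImage | None = None) -> BinaryMask:
    """Read a binary NIfTI mask; optionally check alignment with a reference grid."""
    data, affine, spacing = _load_nifti(path)
    mask = BinaryMask(data=data > 0.5, affine=affine, spacing=spacing)
    if reference is not None and not mask.same_grid_as(reference):
        raise GridAlignmentError(
            f"mask grid {mask.shape} does not match reference grid {reference.shape}"
        )
    return mask


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_dicom_series(directory: str | Path) -> VolumeImage:
    """Convenience wrapper: read a single-series, single-echo DICOM directory.

    Slices are sorted by ImagePositionPatient along the slice normal.  This is
    a thin ingestion path for interactive use; the pipeline's native format is
    NIfTI.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "pixel_array") and hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise UnsupportedImageError(f"no readable DICOM slices under {directory}")
    series = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(series) > 1:
        raise UnsupportedImageError("directory contains more than one DICOM series")
    ori = np.array(slices[0].ImageOrientationPatient, dtype=float)
    row, col = ori[:3], ori[3:]
    normal = np.cross(row, col)
    slices.sort(key=lambda s: float(np.dot(normal, s.ImagePositionPatient)))
    data = np.stack([s.pixel_array.T.astype(float) for s in slices], axis=-1)
    px_r, px_c = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = float(
            np.dot(normal, np.array(slices[1].ImagePositionPatient, dtype=float))
            - np.dot(normal, np.array(slices[0].ImagePositionPatient, dtype=float))
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    affine = np.eye(4)
    affine[:3, 0] = row * px_c
    affine[:3, 1] = col * px_r
    affine[:3, 2] = normal * dz
    affine[:3, 3] = np.array(slices[0].ImagePositionPatient, dtype=float)
    # DICOM LPS -> NIfTI RAS
    affine[:2, :] *= -1
    return VolumeImage(data=data, affine=affine, spacing=(px_c, px_r, abs(dz)))


def voxel_volume_mm3(spacing: Sequence[float]) -> float:
    """Physical volume of one voxel: the product of the in-plane resolution
    factors and the slice thickness, ``sx * sy * sz`` in mm^3."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InvalidGeometryError(f"spacing must be 3 positive values, got {spacing}")
    return spacing[0] * spacing[1] * spacing[2]


def _resample_grid(
    shape: tuple[int, ...],
    spacing: tuple[float, float, float],
    affine: np.ndarray,
    target: float,
) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
    """New grid shape/affine plus the input-index coordinates of output voxels."""
    if target <= 0:
        raise InvalidGeometryError(f"target spacing must be positive, got {target}")
    scale = np.array([target / s for s in spacing])
    new_shape = tuple(
        int(np.ceil(n * s / target)) for n, s in zip(shape, spacing)
    )
    if any(n < 1 for n in new_shape):
        raise InvalidGeometryError(
            f"resampling to {target} mm yields a degenerate grid {new_shape}"
        )
    new_affine = affine.copy()
    new_affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    # input index of output voxel j is simply scale * j (same origin voxel centre)
    grids = np.meshgrid(*(np.arange(n) for n in new_shape), indexing="ij")
    coords = np.stack([g * s for g, s in zip(grids, scale)], axis=0)
    return new_shape, new_affine, coords  # type: ignore[return-value]


def resample_isotropic(
    vol: VolumeImage, target: float = 1.0, interpolation: str = "linear"
) -> VolumeImage:
    """Resample a volume to an isotropic ``target`` mm grid.

    ``interpolation`` is ``"linear"`` (default, never overshoots the input
    intensity range) or ``"nearest"``.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    if np.allclose(vol.spacing, (target,) * 3, atol=1e-9):
        return vol
    _, new_affine, coords = _resample_grid(vol.shape, vol.spacing, vol.affine, target)
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=order, mode="nearest"
    )
    return VolumeImage(data=data, affine=new_affine, spacing=(target,) * 3)


def resample_mask(mask: BinaryMask, target: float = 1.0) -> BinaryMask:
    """Nearest-neighbour resample a mask to an isotropic grid; output is binary."""
    if np.allclose(mask.spacing, (target,) * 3, atol=1e-9):
        return mask
    _, new_affine, coords = _resample_grid(mask.shape, mask.spacing, mask.affine, target)
    data = ndimage.map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="nearest"
    )
    return BinaryMask(data=data.astype(bool), affine=new_affine, spacing=(target,) * 3)
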
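"""Volume containers, NIfTI I/O, FOV cropping and intensity normalisation.

Volumes are stored in a fixed canonical axis order ``(x, y, z)`` where ``x``
runs left-right (sagittal normal), ``y`` anterior-posterior (coronal normal)
and ``z`` inferior-superior (axial normal).  Images arriving in other
orientations are reoriented to the closest canonical form on load.  All
bounding boxes are half-open and voxel coordinates 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "CropRecord",
    "load_volume",
    "load_label",
    "load_case",
    "save_volume",
    "crop_to_brain",
    "uncrop",
    "gaussian_normalise",
]


@dataclass
class ImageVolume:
    """A 3D scalar field with voxel dimensions in mm.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Scalar intensities (float32).
    voxel_size : tuple of float
        Voxel edge lengths in mm per canonical axis; may be anisotropic.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class LabelVolume:
    """A binary 3D mask sharing the grid conventions of :class:`ImageVolume`."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
        # Anything at or above 0.5 counts as foreground (robust to float masks).
        self.data = (arr.astype(np.float64) >= 0.5).astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.voxel_size))


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def load_volume(path: str | Path) -> ImageVolume:
    data, zooms = _read_nifti(path)
    return ImageVolume(data, zooms)


def load_label(path: str | Path) -> LabelVolume:
    data, zooms = _read_nifti(path)
    return LabelVolume(data, zooms)


def save_volume(vol: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with voxel sizes recorded in the affine."""
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


_MASK_KEYS = ("brain", "ventricle", "gm", "csf", "truth", "exclusion", "deep_gm")


def load_case(
    flair_path: str | Path,
    t1_path: str | Path,
    mask_paths: dict[str, str | Path] | None = None,
) -> tuple[ImageVolume, ImageVolume, dict[str, LabelVolume]]:
    """Load a co-registered FLAIR/T1 pair plus any named binary masks.

    All files must share grid shape and voxel size (co-registration is an
    upstream precondition, not performed here); a mismatch raises a
    ``ValueError`` naming the offending file.  Mask values are binarised at
    0.5.
    """
    flair = load_volume(flair_path)
    ref_shape, ref_vox = flair.shape, flair.voxel_size

    def _check(name: str, shape, vox) -> None:
        if shape != ref_shape:
            raise ValueError(
                f"{name}: grid shape {shape} does not match FLAIR {ref_shape}"
            )
        if not np.allclose(vox, ref_vox, rtol=1e-3):
            raise ValueError(
                f"{name}: voxel size {vox} does not match FLAIR {ref_vox}"
            )

    t1 = load_volume(t1_path)
    _check(str(t1_path), t1.shape, t1.voxel_size)

    masks: dict[str, LabelVolume] = {}
    for key, path in (mask_paths or {}).items():
        lab = load_label(path)
        _check(str(path), lab.shape, lab.voxel_size)
        masks[key] = lab
    return flair, t1, masks


@dataclass
class CropRecord:
    """Bounding box of a FOV crop; sufficient to undo the crop exactly."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def cropped_shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))


def crop_to_brain(
    vol: ImageVolume | LabelVolume,
    brain_mask: LabelVolume,
    pad: int = 0,
) -> tuple[ImageVolume | LabelVolume, CropRecord]:
    """Crop the field of view to the brain-mask bounding box plus ``pad`` voxels.

    The box is clipped to the grid.  Returns the cropped volume and a
    :class:`CropRecord` that inverts the crop via :func:`uncrop`.
    """
    mask = brain_mask.as_bool()
    if not mask.any():
        raise ValueError("brain mask is empty; cannot crop")
    if mask.shape != vol.data.shape:
        raise ValueError("volume and brain mask shapes differ")
    start, stop = [], []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        start.append(max(int(idx[0]) - pad, 0))
        stop.append(min(int(idx[-1]) + 1 + pad, mask.shape[ax]))
    rec = CropRecord(tuple(start), tuple(stop), mask.shape)
    cropped = vol.data[rec.slices]
    cls = LabelVolume if isinstance(vol, LabelVolume) else ImageVolume
    return cls(cropped.copy(), vol.voxel_size), rec


def uncrop(vol: ImageVolume | LabelVolume, record: CropRecord) -> ImageVolume | LabelVolume:
    """Embed a cropped volume back into the original grid, zero outside."""
    if vol.data.shape != record.cropped_shape:
        raise ValueError(
            f"volume shape {vol.data.shape} does not match crop record {record.cropped_shape}"
        )
    out = np.zeros(record.original_shape, dtype=vol.data.dtype)
    out[record.slices] = vol.data
    cls = LabelVolume if isinstance(vol, LabelVolume) else ImageVolume
    return cls(out, vol.voxel_size)


def gaussian_normalise(vol: ImageVolume, brain_mask: LabelVolume) -> ImageVolume:
    """Z-score intensities within the brain mask; zero outside.

    After normalisation the in-mask intensities have mean 0 and unit standard
    deviation, making network inputs scale-free across scanners.
    """
    mask = brain_mask.as_bool()
    if mask.shape != vol.data.shape:
        raise ValueError("volume and brain mask shapes differ")
    if not mask.any():
        raise ValueError("brain mask is empty; cannot normalise")
    vals = vol.data[mask].astype(np.float64)
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("in-mask intensities are constant; cannot normalise")
    out = np.zeros_like(vol.data, dtype=np.float32)
    out[mask] = ((vals - float(vals.mean())) / sd).astype(np.float32)
    return ImageVolume(out, vol.voxel_size)
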
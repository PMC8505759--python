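"""Case preprocessing: normalisation, FOV cropping and per-plane arrays.

The preprocessing contract mirrors what a scanner-side pipeline would hand
over after brain extraction, bias correction and co-registration: here it
z-scores intensities within the brain mask, crops the field of view to the
brain (with a small pad), builds the spatial weight map from the anatomy
masks, and turns everything into fixed-size per-plane slice stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio import CropRecord, ImageVolume, LabelVolume, crop_to_brain, gaussian_normalise
from .phantom import PhantomCase
from .planes import DEFAULT_PLANE_SIZES, extract_plane_slices, slice_single_volume
from .train import SubjectSlices
from .weightmaps import build_weight_map

__all__ = ["PreparedCase", "prepare_case", "plane_subject_slices", "volume_sample"]


@dataclass
class PreparedCase:
    """A case after normalisation and FOV cropping (cropped grid)."""

    flair: ImageVolume
    t1: ImageVolume
    brain: LabelVolume
    ventricle: LabelVolume
    gm: LabelVolume
    csf: LabelVolume
    truth: LabelVolume | None
    dwei: np.ndarray
    crop_record: CropRecord
    subject_id: str = ""

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.flair.voxel_size


def prepare_case(case: PhantomCase, pad: int = 2, subject_id: str = "") -> PreparedCase:
    """Normalise, build the weight map, and crop the FOV close to the brain."""
    flair_n = gaussian_normalise(case.flair, case.brain_mask)
    t1_n = gaussian_normalise(case.t1, case.brain_mask)
    wmap = build_weight_map(
        case.ventricle_mask, case.gm_mask, case.brain_mask, case.voxel_size
    )
    flair_c, rec = crop_to_brain(flair_n, case.brain_mask, pad=pad)
    t1_c, _ = crop_to_brain(t1_n, case.brain_mask, pad=pad)

    def _crop_label(lab: LabelVolume) -> LabelVolume:
        return LabelVolume(lab.data[rec.slices].copy(), lab.voxel_size)

    return PreparedCase(
        flair=flair_c,
        t1=t1_c,
        brain=_crop_label(case.brain_mask),
        ventricle=_crop_label(case.ventricle_mask),
        gm=_crop_label(case.gm_mask),
        csf=_crop_label(case.csf_mask),
        truth=_crop_label(case.wmh_truth) if case.wmh_truth is not None else None,
        dwei=wmap.d_wei[rec.slices].copy(),
        crop_record=rec,
        subject_id=subject_id,
    )


def plane_subject_slices(
    prep: PreparedCase,
    plane: str,
    target_size: tuple[int, int] | None = None,
) -> SubjectSlices:
    """Slice one prepared case into training arrays for one plane."""
    if prep.truth is None:
        raise ValueError("cannot build training slices without a lesion label")
    target = tuple(target_size or DEFAULT_PLANE_SIZES[plane])
    sliceset = extract_plane_slices(prep.flair, prep.t1, plane, target)
    labels = slice_single_volume(prep.truth.data, plane, target, order=0)
    labels = (labels >= 0.5).astype(np.uint8)
    dwei = slice_single_volume(prep.dwei, plane, target, order=1)
    return SubjectSlices(
        images=sliceset.data,
        labels=labels,
        dwei=np.maximum(dwei, 0.0).astype(np.float32),
        subject_id=prep.subject_id,
    )


def _pad_to_stride(arr: np.ndarray, stride: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads, sl = [], []
    for s in arr.shape:
        tgt = int(np.ceil(s / stride)) * stride
        before = (tgt - s) // 2
        pads.append((before, tgt - s - before))
        sl.append(slice(before, before + s))
    return np.pad(arr, pads), tuple(sl)


def volume_sample(
    prep: PreparedCase, stride: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[slice, ...]]:
    """Whole-volume arrays for the 3D baseline, padded to the model stride.

    Returns (images (1, 2, X, Y, Z), labels (1, X, Y, Z), dwei (1, X, Y, Z),
    unpad slices to recover the cropped grid).
    """
    flair, sl = _pad_to_stride(prep.flair.data, stride)
    t1, _ = _pad_to_stride(prep.t1.data, stride)
    dwei, _ = _pad_to_stride(prep.dwei, stride)
    img = np.stack([flair, t1])[None].astype(np.float32)
    if prep.truth is not None:
        truth, _ = _pad_to_stride(prep.truth.data, stride)
    else:
        truth = np.zeros_like(flair)
    return img, truth[None].astype(np.uint8), dwei[None].astype(np.float32), sl
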
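"""Conversion between 3D volumes and fixed-size per-plane 2D slice stacks.

Each anatomical plane has a fixed in-plane training size.  Axial slices are
brought to size by centre crop/pad only (no interpolation); sagittal and
coronal slices are resized with bilinear interpolation.  The recorded
geometry makes the mapping invertible so per-slice probability maps can be
reassembled into a 3D map at the source dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .imageio import ImageVolume

__all__ = [
    "DEFAULT_PLANE_SIZES",
    "PLANE_NORMAL_AXIS",
    "PlaneSliceSet",
    "extract_plane_slices",
    "slice_single_volume",
    "reassemble_probabilities",
]

#: in-plane (rows, cols) training size per plane
DEFAULT_PLANE_SIZES: dict[str, tuple[int, int]] = {
    "axial": (128, 192),
    "sagittal": (192, 120),
    "coronal": (128, 80),
}

#: canonical-volume axis normal to each plane (x, y, z) = (0, 1, 2)
PLANE_NORMAL_AXIS: dict[str, int] = {"sagittal": 0, "coronal": 1, "axial": 2}

_PLANES = tuple(PLANE_NORMAL_AXIS)


def _check_plane(plane: str) -> None:
    if plane not in PLANE_NORMAL_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {_PLANES}")


def _centre_crop_pad(stack: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Centre crop/pad the trailing two axes of ``(S, h, w)`` to ``target``."""
    out = stack
    for ax, tgt in zip((1, 2), target):
        src = out.shape[ax]
        if src > tgt:
            a = (src - tgt) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(a, a + tgt)
            out = out[tuple(sl)]
        elif src < tgt:
            before = (tgt - src) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (before, tgt - src - before)
            out = np.pad(out, pad)
    return out


def _centre_crop_pad_inverse(stack: np.ndarray, source: tuple[int, int]) -> np.ndarray:
    """Invert :func:`_centre_crop_pad`: recover in-plane size ``source``.

    Regions cropped away come back as zeros; padded regions are discarded.
    """
    out = stack
    for ax, src in zip((1, 2), source):
        tgt = out.shape[ax]
        if src > tgt:  # was cropped -> pad back with zeros
            a = (src - tgt) // 2
            pad = [(0, 0)] * 3
            pad[ax] = (a, src - tgt - a)
            out = np.pad(out, pad)
        elif src < tgt:  # was padded -> crop back
            before = (tgt - src) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(before, before + src)
            out = out[tuple(sl)]
    return out


def _resize_stack(stack: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    """Resize trailing two axes of ``(S, h, w)``; axis 0 is left untouched."""
    if stack.shape[1:] == tuple(target):
        return stack.astype(np.float32)
    out = _sk_resize(
        stack.astype(np.float32),
        (stack.shape[0], *target),
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(np.float32)


@dataclass
class PlaneSliceSet:
    """Ordered stack of 2-channel (FLAIR, T1) slices for one plane.

    ``data`` has shape ``(S, 2, H, W)`` where ``S`` equals the source extent
    along the plane's normal axis and ``(H, W)`` is the plane's target size.
    ``inplane_shape`` stores the pre-resize in-plane dimensions needed to
    invert the extraction.
    """

    plane: str
    data: np.ndarray
    source_shape: tuple[int, int, int]
    inplane_shape: tuple[int, int]
    target_size: tuple[int, int]

    def __post_init__(self) -> None:
        _check_plane(self.plane)
        if self.data.ndim != 4 or self.data.shape[1] != 2:
            raise ValueError(f"slice data must be (S, 2, H, W), got {self.data.shape}")
        axis = PLANE_NORMAL_AXIS[self.plane]
        if self.data.shape[0] != self.source_shape[axis]:
            raise ValueError("slice count does not match source extent along plane normal")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def _to_stack(vol: np.ndarray, plane: str) -> np.ndarray:
    """Move the plane-normal axis first: returns ``(S, h, w)``."""
    return np.moveaxis(vol, PLANE_NORMAL_AXIS[plane], 0)


def _from_stack(stack: np.ndarray, plane: str) -> np.ndarray:
    return np.moveaxis(stack, 0, PLANE_NORMAL_AXIS[plane])


def slice_single_volume(
    vol: np.ndarray,
    plane: str,
    target_size: tuple[int, int] | None = None,
    order: int = 1,
) -> np.ndarray:
    """Slice one 3D array into a ``(S, H, W)`` stack at the plane target size.

    ``order=1`` gives bilinear resampling (images, probabilities, weight
    maps); ``order=0`` nearest-neighbour (binary labels).  The axial plane
    never interpolates, regardless of ``order``.
    """
    _check_plane(plane)
    target = tuple(target_size or DEFAULT_PLANE_SIZES[plane])
    stack = _to_stack(np.asarray(vol, dtype=np.float32), plane)
    if plane == "axial":
        return _centre_crop_pad(stack, target).astype(np.float32)
    return _resize_stack(stack, target, order=order)


def extract_plane_slices(
    flair: ImageVolume,
    t1: ImageVolume,
    plane: str,
    target_size: tuple[int, int] | None = None,
) -> PlaneSliceSet:
    """Extract the 2-channel slice stack of one plane from a FLAIR/T1 pair."""
    if flair.shape != t1.shape:
        raise ValueError(f"FLAIR shape {flair.shape} != T1 shape {t1.shape}")
    _check_plane(plane)
    target = tuple(target_size or DEFAULT_PLANE_SIZES[plane])
    ch = [slice_single_volume(v.data, plane, target) for v in (flair, t1)]
    axis = PLANE_NORMAL_AXIS[plane]
    inplane = tuple(s for a, s in enumerate(flair.shape) if a != axis)
    return PlaneSliceSet(
        plane=plane,
        data=np.stack(ch, axis=1),
        source_shape=flair.shape,
        inplane_shape=inplane,
        target_size=target,
    )


def reassemble_probabilities(
    slice_probs: np.ndarray,
    plane: str,
    source_shape: tuple[int, int, int],
    clip: bool = True,
) -> np.ndarray:
    """Assemble per-slice probability maps back into a 3D volume.

    ``slice_probs`` has shape ``(S, H, W)`` with one slice per source
    position along the plane normal.  Sagittal/coronal slices are resized
    back with bilinear interpolation; axial crop/pad is inverted exactly.
    Values are clipped to [0, 1] unless ``clip`` is False.
    """
    _check_plane(plane)
    axis = PLANE_NORMAL_AXIS[plane]
    if slice_probs.ndim != 3:
        raise ValueError(f"expected (S, H, W) probabilities, got {slice_probs.shape}")
    if slice_probs.shape[0] != source_shape[axis]:
        raise ValueError(
            f"{slice_probs.shape[0]} slices but source extent along plane normal "
            f"is {source_shape[axis]}"
        )
    inplane = tuple(s for a, s in enumerate(source_shape) if a != axis)
    if plane == "axial":
        stack = _centre_crop_pad_inverse(np.asarray(slice_probs, np.float32), inplane)
    else:
        stack = _resize_stack(np.asarray(slice_probs, np.float32), inplane, order=1)
    vol = _from_stack(stack, plane)
    if clip:
        vol = np.clip(vol, 0.0, 1.0)
    return np.ascontiguousarray(vol, dtype=np.float32)
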
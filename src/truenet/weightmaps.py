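"""Spatial weight maps for the weighted cross-entropy loss.

The weight at a voxel is the sum of two Euclidean distances in mm: the
distance from the ventricles (D_vent, zero on ventricle voxels, growing
toward the cortex) and the distance from the cortical grey matter (D_GM,
zero on GM, growing toward the brain centre).  Their sum D_wei peaks in the
deep white matter, so deep voxels — where lesions are small, punctate and
heavily outnumbered by background — contribute more to the loss than
periventricular ones.  The weights depend only on anatomy (masks and voxel
sizes), never on intensities or lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageio import ImageVolume, LabelVolume

__all__ = ["WeightMap", "distance_from_mask", "build_weight_map"]


@dataclass
class WeightMap:
    """Voxel-wise spatial weights ``d_wei = d_vent + d_gm`` (all in mm).

    ``nd`` and ``md`` are the maxima of ``d_vent`` and ``d_gm`` inside the
    brain mask, so ``0 <= d_wei <= nd + md`` there.
    """

    d_vent: np.ndarray
    d_gm: np.ndarray
    d_wei: np.ndarray
    nd: float
    md: float
    voxel_size: tuple[float, float, float]

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.d_wei.astype(np.float32), self.voxel_size)


def _mask_array(mask: LabelVolume | np.ndarray) -> np.ndarray:
    if isinstance(mask, LabelVolume):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def distance_from_mask(
    mask: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
    domain: LabelVolume | np.ndarray | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Exact Euclidean distance (mm) from each voxel to the nearest mask voxel.

    Anisotropic voxel sizes are honoured via the transform's per-axis
    sampling.  Distance is 0 inside the mask.  If ``domain`` is given the
    field is zeroed outside it (distances are still geometric, computed on
    the full grid).
    """
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("mask is empty; distance field undefined")
    dist = ndimage.distance_transform_edt(~m, sampling=voxel_size)
    dist = np.asarray(dist, dtype=dtype)
    if domain is not None:
        dist = np.where(_mask_array(domain), dist, 0.0).astype(dtype)
    return dist


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with at least one face-neighbour outside it."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def build_weight_map(
    ventricle_mask: LabelVolume | np.ndarray,
    gm_mask: LabelVolume | np.ndarray,
    brain_mask: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
    gm_boundary_only: bool = False,
    scale: float = 1.0,
) -> WeightMap:
    """Build the spatial weight map from ventricle and GM geometry.

    Distances are computed over the whole brain grid and reported raw in mm
    (``scale`` is an optional multiplier on the final map, default 1).  With
    ``gm_boundary_only`` the GM distance is taken from the mask's boundary
    shell rather than the full GM ribbon.
    """
    vent = _mask_array(ventricle_mask)
    gm = _mask_array(gm_mask)
    brain = _mask_array(brain_mask)
    if not vent.any():
        raise ValueError("ventricle mask is empty")
    if not gm.any():
        raise ValueError("GM mask is empty")
    gm_source = _mask_boundary(gm) if gm_boundary_only else gm
    if not gm_source.any():  # single-voxel-thick masks erode to nothing
        gm_source = gm
    d_vent = distance_from_mask(vent, voxel_size)
    d_gm = distance_from_mask(gm_source, voxel_size)
    d_wei = (d_vent + d_gm) * float(scale)
    nd = float(d_vent[brain].max()) if brain.any() else float(d_vent.max())
    md = float(d_gm[brain].max()) if brain.any() else float(d_gm.max())
    return WeightMap(
        d_vent=d_vent,
        d_gm=d_gm,
        d_wei=d_wei.astype(np.float32),
        nd=nd,
        md=md,
        voxel_size=tuple(float(v) for v in voxel_size),
    )
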
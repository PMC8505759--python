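"""Ensemble inference and post-processing to the final binary lesion map.

Each plane network scores its own slice stack; the per-slice probability
maps are reassembled into 3D maps at the original dimensions (zero outside
the cropped FOV) and the three maps are averaged voxel-wise.  The averaged
map is masked to white matter and thresholded at 0.5 (ties count as
lesion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PreparedCase
from .imageio import ImageVolume, LabelVolume, uncrop
from .loss import softmax
from .nn import UNet
from .planes import DEFAULT_PLANE_SIZES, extract_plane_slices, reassemble_probabilities
from .weightmaps import distance_from_mask

__all__ = ["EnsembleOutput", "predict_plane_probability", "predict_case",
           "build_wm_mask", "postprocess"]


@dataclass
class EnsembleOutput:
    """Per-plane and averaged probability maps plus the final binary map."""

    prob_planes: dict[str, ImageVolume]
    prob_final: ImageVolume
    wm_mask: LabelVolume
    binary: LabelVolume


def _forward_batched(net: UNet, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Evaluation-mode WMH-probability maps for a slice stack (S, 2, H, W)."""
    probs = []
    for start in range(0, x.shape[0], batch_size):
        logits = net.forward(x[start : start + batch_size], train=False)
        probs.append(softmax(logits)[:, 1])
    return np.concatenate(probs, axis=0).astype(np.float32)


def predict_plane_probability(
    net: UNet,
    prep: PreparedCase,
    plane: str,
    target_size: tuple[int, int] | None = None,
    batch_size: int = 8,
) -> ImageVolume:
    """One plane's 3D probability map at the original (pre-crop) dimensions."""
    target = tuple(target_size or DEFAULT_PLANE_SIZES[plane])
    sliceset = extract_plane_slices(prep.flair, prep.t1, plane, target)
    slice_probs = _forward_batched(net, sliceset.data, batch_size)
    vol = reassemble_probabilities(slice_probs, plane, prep.flair.shape)
    full = uncrop(ImageVolume(vol, prep.voxel_size), prep.crop_record)
    return full


def build_wm_mask(
    csf_mask: LabelVolume | np.ndarray | None,
    brain_mask: LabelVolume | np.ndarray,
    ventricle_mask: LabelVolume | np.ndarray | None = None,
    deep_gm_exclusions: LabelVolume | np.ndarray | None = None,
    dilation_radius_mm: float = 2.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    """White-matter inclusion mask from a dilated, inverted cortical CSF mask.

    ``brain \\ (dilate(CSF) ∪ ventricles ∪ deep-GM exclusions)``.  The CSF
    dilation radius is in mm (metric, so anisotropic voxels are handled);
    radius 0 inverts the CSF mask exactly.  With no CSF and no exclusions
    the WM mask equals the brain mask.
    """

    def _arr(m):
        return m.as_bool() if isinstance(m, LabelVolume) else np.asarray(m).astype(bool)

    brain = _arr(brain_mask)
    wm = brain.copy()
    if csf_mask is not None:
        csf = _arr(csf_mask)
        if csf.any():
            if dilation_radius_mm > 0:
                csf = distance_from_mask(csf, voxel_size) <= dilation_radius_mm
            wm &= ~csf
    if ventricle_mask is not None:
        wm &= ~_arr(ventricle_mask)
    if deep_gm_exclusions is not None:
        wm &= ~_arr(deep_gm_exclusions)
    if not wm.any():
        import warnings

        warnings.warn("white-matter mask is empty (degenerate exclusion masks)")
    return LabelVolume(wm, tuple(voxel_size))


def postprocess(
    probs: ImageVolume | np.ndarray,
    wm_mask: LabelVolume | np.ndarray,
    threshold: float = 0.5,
) -> LabelVolume:
    """Mask the probability map to white matter and threshold (>= counts in)."""
    p = probs.data if isinstance(probs, ImageVolume) else np.asarray(probs)
    wm = wm_mask.as_bool() if isinstance(wm_mask, LabelVolume) else np.asarray(wm_mask).astype(bool)
    if p.shape != wm.shape:
        raise ValueError("probability map and WM mask shapes differ")
    vs = probs.voxel_size if isinstance(probs, ImageVolume) else (1.0, 1.0, 1.0)
    return LabelVolume((p >= threshold) & wm, vs)


def predict_case(
    models: dict[str, UNet],
    prep: PreparedCase,
    plane_sizes: dict[str, tuple[int, int]] | None = None,
    threshold: float = 0.5,
    dilation_radius_mm: float = 2.0,
    deep_gm_exclusions: LabelVolume | np.ndarray | None = None,
    batch_size: int = 8,
) -> EnsembleOutput:
    """Full ensemble inference for one prepared case.

    ``models`` maps plane names to trained networks; with all three planes
    the final map is their voxel-wise mean, with a single plane it is that
    plane's map.  Deterministic in evaluation mode.
    """
    if not models:
        raise ValueError("no trained plane models given")
    sizes = plane_sizes or {}
    prob_planes: dict[str, ImageVolume] = {}
    for plane, net in models.items():
        prob_planes[plane] = predict_plane_probability(
            net, prep, plane, sizes.get(plane), batch_size
        )
    stack = np.stack([v.data for v in prob_planes.values()])
    # accumulate in float64 so the averaged map is independent of plane order
    prob_final = ImageVolume(
        stack.astype(np.float64).mean(axis=0).astype(np.float32), prep.voxel_size
    )

    rec = prep.crop_record
    full = lambda lab: LabelVolume(  # noqa: E731 - embed cropped masks in the full grid
        uncrop(lab, rec).data, prep.voxel_size
    )
    wm = build_wm_mask(
        full(prep.csf),
        full(prep.brain),
        ventricle_mask=full(prep.ventricle),
        deep_gm_exclusions=deep_gm_exclusions,
        dilation_radius_mm=dilation_radius_mm,
        voxel_size=prep.voxel_size,
    )
    binary = postprocess(prob_final, wm, threshold)
    return EnsembleOutput(
        prob_planes=prob_planes, prob_final=prob_final, wm_mask=wm, binary=binary
    )
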
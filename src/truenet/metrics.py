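"""Segmentation evaluation metrics, whole-brain and per-compartment.

Voxel-wise: Dice similarity index (SI), true/false positive rates.
Cluster-wise: lesions are 26-connected components; a true cluster counts as
detected if any of its voxels is predicted, a predicted cluster as a true
positive if it overlaps any manual voxel.  Volume: absolute volume
difference as a percentage of the manual lesion volume.  Surface: 95th
percentile of the pooled symmetric set of boundary closest distances (H95),
a noise-robust Hausdorff variant.  The periventricular/deep split follows
the 10 mm distance-from-ventricles rule.

Conventions for degenerate inputs: Dice of two empty masks is 1.0 and of an
empty-vs-nonempty pair 0.0; rates whose denominator is empty are reported as
``None`` (missing), as is H95 when either mask is empty; AVD with an empty
manual mask is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .imageio import LabelVolume
from .weightmaps import distance_from_mask

__all__ = [
    "MetricsReport",
    "dice_si",
    "voxel_rates",
    "cluster_metrics",
    "avd",
    "hausdorff95",
    "split_pwmh_dwmh",
    "evaluate_case",
    "aggregate_reports",
]

PV_DISTANCE_MM = 10.0


def _arr(mask: LabelVolume | np.ndarray) -> np.ndarray:
    if isinstance(mask, LabelVolume):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def dice_si(pred: LabelVolume | np.ndarray, manual: LabelVolume | np.ndarray) -> float:
    """Dice similarity index 2|P∩M| / (|M| + |P|)."""
    p, m = _arr(pred), _arr(manual)
    if p.shape != m.shape:
        raise ValueError("masks must share a grid")
    denom = int(p.sum()) + int(m.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & m).sum()) / denom


def voxel_rates(
    pred: LabelVolume | np.ndarray,
    manual: LabelVolume | np.ndarray,
    brain_mask: LabelVolume | np.ndarray,
) -> tuple[float | None, float | None]:
    """Voxel-wise (TPR, FPR); FPR uses non-lesion voxels inside the brain."""
    p, m, b = _arr(pred), _arr(manual), _arr(brain_mask)
    if not (p.shape == m.shape == b.shape):
        raise ValueError("masks must share a grid")
    n_pos = int(m.sum())
    tpr = int((p & m).sum()) / n_pos if n_pos else None
    neg = b & ~m
    n_neg = int(neg.sum())
    fpr = int((p & neg).sum()) / n_neg if n_neg else None
    return tpr, fpr


def _clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    lab, n = cc_label(mask, connectivity=mask.ndim, return_num=True)
    return lab, n


def cluster_metrics(
    pred: LabelVolume | np.ndarray, manual: LabelVolume | np.ndarray
) -> tuple[float | None, float | None, float | None]:
    """Cluster-wise (TPR, precision, F1) under 26-connectivity."""
    p, m = _arr(pred), _arr(manual)
    if p.shape != m.shape:
        raise ValueError("masks must share a grid")
    m_lab, n_true = _clusters(m)
    p_lab, n_pred = _clusters(p)
    tpr = None
    if n_true:
        detected = len(np.unique(m_lab[p & (m_lab > 0)]))
        tpr = detected / n_true
    precision = None
    if n_pred:
        hits = len(np.unique(p_lab[m & (p_lab > 0)]))
        precision = hits / n_pred
    f1 = None
    if tpr is not None and precision is not None and (tpr + precision) > 0:
        f1 = 2.0 * tpr * precision / (tpr + precision)
    elif tpr is not None and precision is not None:
        f1 = 0.0
    return tpr, precision, f1


def avd(
    pred: LabelVolume | np.ndarray,
    manual: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
) -> float:
    """Absolute volume difference as a percentage of the manual volume."""
    p, m = _arr(pred), _arr(manual)
    if p.shape != m.shape:
        raise ValueError("masks must share a grid")
    voxvol = float(np.prod(voxel_size))
    v_man = int(m.sum()) * voxvol
    if v_man == 0:
        raise ValueError("manual mask is empty; AVD undefined")
    v_pred = int(p.sum()) * voxvol
    return abs(v_pred - v_man) / v_man * 100.0


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1)
    )
    return mask & ~eroded


def hausdorff95(
    pred: LabelVolume | np.ndarray,
    manual: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
    symmetric: bool = True,
) -> float | None:
    """95th percentile of boundary closest-distance values, in mm.

    Distances are measured between boundary voxels of the two masks; both
    directed sets are pooled by default (``symmetric=False`` keeps only
    prediction-to-manual).  Returns ``None`` when either mask is empty.
    """
    p, m = _arr(pred), _arr(manual)
    if p.shape != m.shape:
        raise ValueError("masks must share a grid")
    if not p.any() or not m.any():
        return None
    bp, bm = _boundary(p), _boundary(m)
    d_to_m = distance_from_mask(bm, voxel_size, dtype=np.float64)
    dists = [d_to_m[bp]]
    if symmetric:
        d_to_p = distance_from_mask(bp, voxel_size, dtype=np.float64)
        dists.append(d_to_p[bm])
    pooled = np.concatenate(dists)
    return float(np.percentile(pooled, 95))


def split_pwmh_dwmh(
    mask: LabelVolume | np.ndarray,
    ventricle_mask: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Split a lesion mask into periventricular (<10 mm) and deep (>=10 mm).

    The split is voxel-wise, so a cluster straddling the 10 mm shell
    contributes to both compartments; the two outputs partition the input.
    """
    m = _arr(mask)
    d_vent = distance_from_mask(ventricle_mask, voxel_size)
    pwmh = m & (d_vent < PV_DISTANCE_MM)
    dwmh = m & (d_vent >= PV_DISTANCE_MM)
    return pwmh, dwmh


@dataclass
class MetricsReport:
    """All evaluation metrics for one case (optionally per compartment)."""

    si: float
    tpr_voxel: float | None
    fpr_voxel: float | None
    tpr_cluster: float | None
    precision_cluster: float | None
    f1_cluster: float | None
    avd_percent: float | None
    h95: float | None
    volume_manual_mm3: float = 0.0
    volume_pred_mm3: float = 0.0
    per_region: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "si": self.si,
            "tpr_voxel": self.tpr_voxel,
            "fpr_voxel": self.fpr_voxel,
            "tpr_cluster": self.tpr_cluster,
            "precision_cluster": self.precision_cluster,
            "f1_cluster": self.f1_cluster,
            "avd_percent": self.avd_percent,
            "h95": self.h95,
            "volume_manual_mm3": self.volume_manual_mm3,
            "volume_pred_mm3": self.volume_pred_mm3,
        }
        if self.per_region:
            d["per_region"] = {k: v.to_dict() for k, v in self.per_region.items()}
        return d


def _single_report(
    pred: np.ndarray,
    manual: np.ndarray,
    brain: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> MetricsReport:
    tpr_v, fpr_v = voxel_rates(pred, manual, brain)
    tpr_c, prec_c, f1_c = cluster_metrics(pred, manual)
    voxvol = float(np.prod(voxel_size))
    avd_val = avd(pred, manual, voxel_size) if manual.any() else None
    return MetricsReport(
        si=dice_si(pred, manual),
        tpr_voxel=tpr_v,
        fpr_voxel=fpr_v,
        tpr_cluster=tpr_c,
        precision_cluster=prec_c,
        f1_cluster=f1_c,
        avd_percent=avd_val,
        h95=hausdorff95(pred, manual, voxel_size),
        volume_manual_mm3=float(manual.sum()) * voxvol,
        volume_pred_mm3=float(pred.sum()) * voxvol,
    )


def evaluate_case(
    pred: LabelVolume | np.ndarray,
    manual: LabelVolume | np.ndarray,
    brain_mask: LabelVolume | np.ndarray,
    voxel_size: tuple[float, float, float],
    ventricle_mask: LabelVolume | np.ndarray | None = None,
) -> MetricsReport:
    """Full metrics report; regional sub-reports when a ventricle mask is given."""
    p, m, b = _arr(pred), _arr(manual), _arr(brain_mask)
    report = _single_report(p, m, b, voxel_size)
    if ventricle_mask is not None:
        d_vent = distance_from_mask(ventricle_mask, voxel_size)
        for name, region in (
            ("pwmh", d_vent < PV_DISTANCE_MM),
            ("dwmh", d_vent >= PV_DISTANCE_MM),
        ):
            report.per_region[name] = _single_report(
                p & region, m & region, b & region, voxel_size
            )
    return report


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Cohort medians and IQRs of every scalar metric (missing values skipped)."""
    keys = [
        "si",
        "tpr_voxel",
        "fpr_voxel",
        "tpr_cluster",
        "precision_cluster",
        "f1_cluster",
        "avd_percent",
        "h95",
    ]
    out: dict[str, dict[str, float]] = {}
    for key in keys:
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        out[key] = {
            "median": float(np.median(arr)),
            "iqr_low": float(np.percentile(arr, 25)),
            "iqr_high": float(np.percentile(arr, 75)),
            "n": int(arr.size),
        }
    return out
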
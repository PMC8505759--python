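"""Composite training objective: spatially weighted cross-entropy + Dice.

The cross-entropy term is weighted voxel-wise by the anatomical distance map
(``d_wei``), up-weighting the deep white matter where lesions are scarce and
class imbalance extreme.  The Dice term rewards overlap directly, which
favours small lesions whose voxels barely register in the cross-entropy sum.
The two terms are added with equal (unit) weights by default:

    L = CE + DcL,   CE >= 0,   -1 <= DcL <= 0.

The printed Dice definition uses the thresholded binary prediction, which
has no gradient; training therefore uses the *soft* Dice (probabilities in
place of the binary map), and the hard variant is kept for monitoring.
Cross-entropy is averaged over the voxels of the batch so the magnitude is
batch-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOSS_VARIANTS",
    "LossBatch",
    "softmax",
    "one_hot",
    "weighted_ce",
    "dice_loss",
    "total_loss",
    "total_loss_and_grad",
]

EPS_LOG = 1e-7      # clamp for log(p)

LOSS_VARIANTS = ("weighted_ce_plus_dice", "weighted_ce", "ce_only", "dice_only")
_VARIANT_ALIASES = {"weighted_ce_only": "weighted_ce"}


def normalise_variant(variant: str) -> str:
    v = _VARIANT_ALIASES.get(variant, variant)
    if v not in LOSS_VARIANTS:
        raise ValueError(f"unknown loss variant {variant!r}; expected one of {LOSS_VARIANTS}")
    return v


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Binary label array ``(N, *S)`` -> one-hot ``(N, C, *S)`` float32."""
    lab = np.asarray(labels)
    out = np.zeros((lab.shape[0], n_classes, *lab.shape[1:]), dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = lab == c
    return out


@dataclass
class LossBatch:
    """Aligned tensors entering the loss.

    ``p``: softmax class probabilities ``(N, C, *S)``; ``y``: one-hot labels
    of the same shape; ``dwei``: per-voxel spatial weights ``(N, *S)`` or
    None for unweighted CE; ``pth``: thresholded binary prediction, only
    needed for the hard (monitoring) Dice.
    """

    p: np.ndarray
    y: np.ndarray
    dwei: np.ndarray | None = None
    pth: np.ndarray | None = None

    def __post_init__(self) -> None:
        p, y = np.asarray(self.p), np.asarray(self.y)
        if p.shape != y.shape:
            raise ValueError(f"p shape {p.shape} != y shape {y.shape}")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("probabilities do not sum to 1 over classes")
        if not np.array_equal(np.unique(y), np.unique(y).round()):
            raise ValueError("labels must be one-hot")
        if self.dwei is not None:
            dwei = np.asarray(self.dwei)
            if dwei.shape != (p.shape[0], *p.shape[2:]):
                raise ValueError(f"dwei shape {dwei.shape} incompatible with p {p.shape}")
            if dwei.min() < 0:
                raise ValueError("spatial weights must be >= 0")


def weighted_ce(batch: LossBatch) -> float:
    """Spatially weighted cross-entropy, averaged over batch voxels.

    Reduces to the standard cross-entropy when the weight map is identically
    one (or absent).
    """
    p = np.clip(np.asarray(batch.p, dtype=np.float64), EPS_LOG, 1.0)
    y = np.asarray(batch.y, dtype=np.float64)
    n_vox = y.shape[0] * int(np.prod(y.shape[2:]))
    ce_vox = -(y * np.log(p)).sum(axis=1)  # (N, *S)
    if batch.dwei is not None:
        ce_vox = ce_vox * np.asarray(batch.dwei, dtype=np.float64)
    return float(ce_vox.sum() / n_vox)


def dice_loss(batch: LossBatch, mode: str = "soft") -> float:
    """Dice loss -2|M∩P| / (|M| + |P|), in [-1, 0].

    ``soft`` uses the WMH-class probability, ``hard`` the thresholded binary
    map (requires ``pth``).  When both masks are empty the loss is defined
    as -1 (perfect agreement); otherwise the formula is applied exactly.
    """
    m = np.asarray(batch.y, dtype=np.float64)[:, 1]
    if mode == "soft":
        pred = np.asarray(batch.p, dtype=np.float64)[:, 1]
    elif mode == "hard":
        if batch.pth is None:
            raise ValueError("hard Dice requires the thresholded prediction pth")
        pred = np.asarray(batch.pth, dtype=np.float64)
    else:
        raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
    num = 2.0 * (m * pred).sum()
    den = m.sum() + pred.sum()
    if den == 0.0:
        return -1.0
    return float(-num / den)


def total_loss(batch: LossBatch, ce_weight: float = 1.0, dice_weight: float = 1.0,
               mode: str = "soft") -> float:
    """Composite loss L = ce_weight * CE + dice_weight * DcL."""
    return ce_weight * weighted_ce(batch) + dice_weight * dice_loss(batch, mode=mode)


def total_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    dwei: np.ndarray | None,
    variant: str = "weighted_ce_plus_dice",
    ce_weight: float = 1.0,
    dice_weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits.

    ``logits``: ``(N, C, *S)``; ``labels``: binary ``(N, *S)``; ``dwei``:
    spatial weights or None.  The CE gradient is the familiar softmax
    residual ``w * (p - y) / n_vox``; the soft-Dice gradient flows through
    the WMH-probability channel of the softmax.
    """
    variant = normalise_variant(variant)
    p = softmax(logits.astype(np.float64))
    y = one_hot(labels, logits.shape[1]).astype(np.float64)
    n_vox = y.shape[0] * int(np.prod(y.shape[2:]))
    w = None
    if variant in ("weighted_ce_plus_dice", "weighted_ce") and dwei is not None:
        w = np.asarray(dwei, dtype=np.float64)

    loss = 0.0
    dlogits = np.zeros_like(p)

    if variant != "dice_only":
        ce_vox = -(y * np.log(np.clip(p, EPS_LOG, 1.0))).sum(axis=1)
        g = (p - y) / n_vox
        if w is not None:
            ce_vox = ce_vox * w
            g = g * w[:, None]
        loss += ce_weight * float(ce_vox.sum() / n_vox)
        dlogits += ce_weight * g

    if variant in ("weighted_ce_plus_dice", "dice_only"):
        m = y[:, 1]
        p1 = p[:, 1]
        num = 2.0 * (m * p1).sum()
        den = m.sum() + p1.sum()
        if den == 0.0:
            loss += dice_weight * -1.0
        else:
            loss += dice_weight * float(-num / den)
            g1 = dice_weight * (-(2.0 * m * den - num) / den**2)
            jac = p1 * (1.0 - p1)  # d p1 / d z1 = -d p1 / d z0 for two classes
            dlogits[:, 1] += g1 * jac
            dlogits[:, 0] -= g1 * jac
    return float(loss), dlogits.astype(np.float32)
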
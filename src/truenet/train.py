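"""Training: augmentation, LR schedule, early stopping, per-plane loops.

Training is subject-wise: the validation split is over subjects, never over
slices, so no slice of a held-out subject leaks into training.  Augmented
copies are drawn on the fly from a seeded generator rather than
materialised; the per-plane ``factor`` sets how many draws each slice
contributes per epoch (the first copy is the unaugmented slice).  All
randomness — split, shuffling, augmentation — derives from one seed, so two
runs with the same configuration produce identical loss histories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .loss import normalise_variant, total_loss_and_grad
from .nn import Adam, UNet

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "lr_at_epoch",
    "sample_augmentation",
    "apply_augmentation",
    "augment_slice",
    "train_plane",
    "SubjectSlices",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults: Adam (eps 1e-4), batch size 8, learning rate starting at 1e-3
    and decaying by 0.1 every 2 epochs down to a floor of 1e-5, early
    stopping with a patience of 20 epochs on the validation loss, and a
    90/10 subject-wise train/validation split.
    """

    batch_size: int = 8
    lr_init: float = 1e-3
    lr_floor: float = 1e-5
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 2
    adam_eps: float = 1e-4
    patience: int = 20
    max_epochs: int = 100
    val_fraction: float = 0.10
    loss_variant: str = "weighted_ce_plus_dice"
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_floor <= self.lr_init):
            raise ValueError("need 0 < lr_floor <= lr_init")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        normalise_variant(self.loss_variant)


@dataclass(frozen=True)
class AugmentConfig:
    """Data augmentation ranges (closed intervals, sampled uniformly).

    Geometric transforms (translation in voxels, rotation in degrees) are
    applied identically to images, labels and weight maps; noise and blur
    touch intensities only.  ``factor_axial``/``factor_sagcor`` give the
    number of copies of each slice per epoch.
    """

    translate_range: float = 10.0
    rotate_range: float = 10.0
    noise_var_range: tuple[float, float] = (0.01, 0.09)
    blur_sigma_range: tuple[float, float] = (0.1, 0.3)
    factor_axial: int = 10
    factor_sagcor: int = 6

    def __post_init__(self) -> None:
        if self.factor_axial < 1 or self.factor_sagcor < 1:
            raise ValueError("augmentation factors must be >= 1")
        if self.translate_range < 0 or self.rotate_range < 0:
            raise ValueError("ranges must be non-negative")

    def factor_for(self, plane: str) -> int:
        return self.factor_axial if plane == "axial" else self.factor_sagcor


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: lr_init * factor^(epoch // every), floored."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    lr = cfg.lr_init * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)
    return max(lr, cfg.lr_floor)


def sample_augmentation(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    return {
        "offset": tuple(rng.uniform(-cfg.translate_range, cfg.translate_range, size=2)),
        "angle": float(rng.uniform(-cfg.rotate_range, cfg.rotate_range)),
        "noise_var": float(rng.uniform(*cfg.noise_var_range)),
        "blur_sigma": float(rng.uniform(*cfg.blur_sigma_range)),
    }


def apply_augmentation(
    image_pair: np.ndarray,
    label: np.ndarray,
    dwei: np.ndarray | None,
    offset: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
    noise_var: float = 0.0,
    blur_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Apply one transform combination; identity at all-zero parameters."""

    def _geom(arr: np.ndarray, order: int) -> np.ndarray:
        out = arr.astype(np.float32)
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False, order=order,
                                 mode="constant", cval=0.0)
        if offset[0] != 0.0 or offset[1] != 0.0:
            out = ndimage.shift(out, offset, order=order, mode="constant", cval=0.0)
        return out

    images = np.stack([_geom(ch, order=1) for ch in image_pair])
    if noise_var > 0:
        if rng is None:
            raise ValueError("noise injection requires an rng")
        images = images + rng.normal(0.0, np.sqrt(noise_var), size=images.shape)
    if blur_sigma > 0:
        images = np.stack([ndimage.gaussian_filter(ch, blur_sigma) for ch in images])
    new_label = _geom(label, order=0)
    new_label = (new_label >= 0.5).astype(label.dtype)
    new_dwei = _geom(dwei, order=1) if dwei is not None else None
    return images.astype(np.float32), new_label, new_dwei


def augment_slice(
    image_pair: np.ndarray,
    label: np.ndarray,
    dwei: np.ndarray | None,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Random draw from the augmentation ranges applied to one slice triple."""
    params = sample_augmentation(cfg, rng)
    return apply_augmentation(image_pair, label, dwei, rng=rng, **params)


@dataclass
class SubjectSlices:
    """One subject's slice arrays for a single plane.

    ``images``: (S, 2, H, W); ``labels``: (S, H, W) binary; ``dwei``:
    (S, H, W) spatial weights (may be None for unweighted variants).
    """

    images: np.ndarray
    labels: np.ndarray
    dwei: np.ndarray | None = None
    subject_id: str = ""

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]


def _split_subjects(
    n: int, val_fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    order = list(rng.permutation(n))
    if n < 2:
        return order, order  # degenerate: validate on the only subject
    n_val = min(n - 1, max(1, int(round(val_fraction * n))))
    return order[n_val:], order[:n_val]


def _run_batches(
    net: UNet,
    batches: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]],
    cfg: TrainConfig,
    optimiser: Adam | None,
) -> float:
    """Run batches (train if an optimiser is given); return mean loss."""
    total, count = 0.0, 0
    train = optimiser is not None
    for x, y, w in batches:
        logits = net.forward(x, train=train)
        loss, dlogits = total_loss_and_grad(
            logits, y, w, variant=cfg.loss_variant,
            ce_weight=cfg.ce_weight, dice_weight=cfg.dice_weight,
        )
        if train:
            optimiser.zero_grad()
            net.backward(dlogits)
            optimiser.step()
        total += loss * x.shape[0]
        count += x.shape[0]
    return total / max(count, 1)


def _make_batches(samples, subjects, cfg, aug_cfg, rng, augment):
    batches = []
    bs = cfg.batch_size
    for start in range(0, len(samples), bs):
        chunk = samples[start : start + bs]
        xs, ys, ws = [], [], []
        for subj_idx, slice_idx, aug_flag in chunk:
            subj = subjects[subj_idx]
            img = subj.images[slice_idx]
            lab = subj.labels[slice_idx]
            dw = subj.dwei[slice_idx] if subj.dwei is not None else None
            if augment and aug_flag:
                img, lab, dw = augment_slice(img, lab, dw, aug_cfg, rng)
            xs.append(img)
            ys.append(lab)
            ws.append(dw)
        x = np.stack(xs).astype(np.float32)
        y = np.stack(ys)
        w = None if ws[0] is None else np.stack(ws).astype(np.float32)
        batches.append((x, y, w))
    return batches


def train_plane(
    net: UNet,
    subjects: list[SubjectSlices],
    cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
    plane: str = "axial",
    freeze: bool = False,
) -> tuple[list[dict], dict]:
    """Train one plane network; returns (history, best_state).

    Early stopping: training ends once the validation loss has failed to
    improve (strict decrease by more than 1e-6) for ``cfg.patience``
    consecutive epochs; the best-validation weights are restored into
    ``net`` and returned.  ``freeze`` skips the optimiser step (diagnostic:
    a frozen model can never improve, so stopping must fire after exactly
    ``patience`` stalled epochs).
    """
    if not subjects:
        raise ValueError("empty training set")
    aug_cfg = aug_cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _split_subjects(len(subjects), cfg.val_fraction, rng)
    if not train_idx:
        raise ValueError("empty training split")
    factor = aug_cfg.factor_for(plane)

    optimiser = Adam(net.parameters(), lr=cfg.lr_init, eps=cfg.adam_eps)
    val_samples = [(s, k, False) for s in val_idx for k in range(subjects[s].n_slices)]
    val_batches = _make_batches(val_samples, subjects, cfg, aug_cfg, rng, augment=False)

    history: list[dict] = []
    best_val = np.inf
    best_state: dict = net.state_dict()
    stalled = 0
    for epoch in range(cfg.max_epochs):
        optimiser.lr = lr_at_epoch(epoch, cfg)
        samples = [
            (s, k, copy_i > 0)
            for s in train_idx
            for k in range(subjects[s].n_slices)
            for copy_i in range(factor)
        ]
        order = rng.permutation(len(samples))
        samples = [samples[i] for i in order]
        batches = _make_batches(samples, subjects, cfg, aug_cfg, rng, augment=True)
        train_loss = _run_batches(net, batches, cfg, None if freeze else optimiser)
        val_loss = _run_batches(net, val_batches, cfg, None)
        history.append(
            {"epoch": epoch, "lr": optimiser.lr, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.state_dict()
            stalled = 0
        else:
            stalled += 1
            if stalled >= cfg.patience:
                break
    net.load_state_dict(best_state)
    return history, best_state
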
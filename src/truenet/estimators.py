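"""Scikit-learn style estimator for triplanar WMH segmentation.

:class:`WMHSegmenter` wraps the preprocessing, per-plane training and
ensemble inference behind ``fit`` / ``predict`` / ``predict_proba``, so it
composes with sklearn model selection utilities.  ``X`` is a list of cases
(:class:`~truenet.phantom.PhantomCase` or objects with the same fields);
the manual lesion masks travel with the cases, or may be passed as ``y``.
"""

from __future__ import annotations

import zlib

import numpy as np
from sklearn.base import BaseEstimator

from .data import PreparedCase, plane_subject_slices, prepare_case, volume_sample
from .imageio import ImageVolume, LabelVolume, uncrop
from .infer import EnsembleOutput, build_wm_mask, postprocess, predict_case
from .loss import softmax
from .metrics import MetricsReport, dice_si, evaluate_case
from .nn import UNet, UNetConfig, build_3d_unet, build_unet
from .planes import DEFAULT_PLANE_SIZES
from .train import AugmentConfig, SubjectSlices, TrainConfig, train_plane

__all__ = ["WMHSegmenter", "PLANES"]

PLANES = ("axial", "sagittal", "coronal")

_MODEL_DIMS = ("triplanar", "2d_axial", "3d")


class WMHSegmenter(BaseEstimator):
    """Triplanar ensemble U-Net segmenter (with 2D-axial and 3D baselines).

    Parameters follow the established training recipe: shallow (3-level)
    per-plane U-Nets with 5x5 first kernels in the sagittal/coronal planes,
    spatially weighted cross-entropy + Dice loss, Adam with step-decayed
    learning rate and patience-based early stopping.  ``plane_sizes`` may
    shrink the fixed per-plane slice sizes for small-volume work; ``None``
    uses the standard sizes.

    Attributes set by :meth:`fit` (trailing underscore): ``models_`` maps
    plane names (or ``"3d"``) to trained networks, ``history_`` the per-plane
    loss curves, ``n_parameters_`` the total trainable parameter count.
    """

    def __init__(
        self,
        model_dim: str = "triplanar",
        depth: int = 3,
        base_channels: int = 64,
        unet3d_depth: int = 4,
        plane_sizes: dict[str, tuple[int, int]] | None = None,
        loss_variant: str = "weighted_ce_plus_dice",
        ce_weight: float = 1.0,
        dice_weight: float = 1.0,
        batch_size: int = 8,
        lr_init: float = 1e-3,
        lr_floor: float = 1e-5,
        lr_decay_factor: float = 0.1,
        lr_decay_every: int = 2,
        adam_eps: float = 1e-4,
        max_epochs: int | dict = 100,
        patience: int = 20,
        val_fraction: float = 0.10,
        translate_range: float = 10.0,
        rotate_range: float = 10.0,
        noise_var_range: tuple[float, float] = (0.01, 0.09),
        blur_sigma_range: tuple[float, float] = (0.1, 0.3),
        factor_axial: int = 10,
        factor_sagcor: int = 6,
        crop_pad: int = 2,
        threshold: float = 0.5,
        dilation_radius_mm: float = 2.0,
        random_state: int = 0,
    ):
        self.model_dim = model_dim
        self.depth = depth
        self.base_channels = base_channels
        self.unet3d_depth = unet3d_depth
        self.plane_sizes = plane_sizes
        self.loss_variant = loss_variant
        self.ce_weight = ce_weight
        self.dice_weight = dice_weight
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.lr_floor = lr_floor
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.adam_eps = adam_eps
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.translate_range = translate_range
        self.rotate_range = rotate_range
        self.noise_var_range = noise_var_range
        self.blur_sigma_range = blur_sigma_range
        self.factor_axial = factor_axial
        self.factor_sagcor = factor_sagcor
        self.crop_pad = crop_pad
        self.threshold = threshold
        self.dilation_radius_mm = dilation_radius_mm
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _max_epochs(self, plane: str) -> int:
        """Per-plane epoch budget (``max_epochs`` may be an int or a dict).

        Planes differ in slices per subject, hence in optimiser steps per
        epoch; a dict lets small-scale runs balance the step budget.
        """
        if isinstance(self.max_epochs, dict):
            return int(self.max_epochs.get(plane, max(self.max_epochs.values())))
        return int(self.max_epochs)

    def _train_cfg(self, plane: str = "axial") -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            lr_init=self.lr_init,
            lr_floor=self.lr_floor,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_every=self.lr_decay_every,
            adam_eps=self.adam_eps,
            patience=self.patience,
            max_epochs=self._max_epochs(plane),
            val_fraction=self.val_fraction,
            loss_variant=self.loss_variant,
            ce_weight=self.ce_weight,
            dice_weight=self.dice_weight,
            seed=int(self.random_state),
        )

    def _aug_cfg(self, factor_override: int | None = None) -> AugmentConfig:
        return AugmentConfig(
            translate_range=self.translate_range,
            rotate_range=self.rotate_range,
            noise_var_range=self.noise_var_range,
            blur_sigma_range=self.blur_sigma_range,
            factor_axial=factor_override or self.factor_axial,
            factor_sagcor=factor_override or self.factor_sagcor,
        )

    def _plane_size(self, plane: str) -> tuple[int, int]:
        sizes = self.plane_sizes or {}
        return tuple(sizes.get(plane, DEFAULT_PLANE_SIZES[plane]))

    def _seed_for(self, tag: str) -> int:
        # stable across processes (never use hash() here: it is salted)
        digest = zlib.crc32(tag.encode("utf-8"))
        return (int(self.random_state) * 1000003 + digest % 9973) % 2**31

    def _prepare(self, X, y=None) -> list[PreparedCase]:
        preps = []
        for i, case in enumerate(X):
            if y is not None:
                case = _with_truth(case, y[i])
            preps.append(prepare_case(case, pad=self.crop_pad, subject_id=str(i)))
        return preps

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "WMHSegmenter":
        """Train the plane networks on a list of cases.

        ``X``: list of cases with FLAIR/T1 and anatomy masks; lesion labels
        come from each case's ``wmh_truth`` unless ``y`` (list of masks) is
        given.
        """
        if self.model_dim not in _MODEL_DIMS:
            raise ValueError(f"model_dim must be one of {_MODEL_DIMS}")
        if not X:
            raise ValueError("empty training set")
        preps = self._prepare(X, y)
        self.models_: dict[str, UNet] = {}
        self.history_: dict[str, list[dict]] = {}

        if self.model_dim == "3d":
            net = build_3d_unet(
                base_channels=self.base_channels,
                depth=self.unet3d_depth,
                seed=self._seed_for("3d"),
            )
            stride = 2 ** (self.unet3d_depth - 1)
            subjects = []
            for prep in preps:
                img, lab, dwei, _ = volume_sample(prep, stride)
                subjects.append(SubjectSlices(img, lab, dwei, prep.subject_id))
            cfg = self._train_cfg("3d")
            cfg3d = TrainConfig(**{**_cfg_dict(cfg), "batch_size": min(cfg.batch_size, 2)})
            hist, _ = train_plane(net, subjects, cfg3d, self._aug_cfg(factor_override=1),
                                  plane="axial")
            self.models_["3d"] = net
            self.history_["3d"] = hist
        else:
            planes = ("axial",) if self.model_dim == "2d_axial" else PLANES
            for plane in planes:
                first_kernel = 3 if plane == "axial" else 5
                net = build_unet(
                    UNetConfig(
                        depth=self.depth,
                        base_channels=self.base_channels,
                        first_kernel=first_kernel,
                    ),
                    seed=self._seed_for(plane),
                )
                subjects = [
                    plane_subject_slices(prep, plane, self._plane_size(plane))
                    for prep in preps
                ]
                hist, _ = train_plane(net, subjects, self._train_cfg(plane),
                                      self._aug_cfg(), plane=plane)
                self.models_[plane] = net
                self.history_[plane] = hist

        self.n_parameters_ = sum(net.n_parameters() for net in self.models_.values())
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def _predict_prep(self, prep: PreparedCase) -> EnsembleOutput:
        if self.model_dim == "3d":
            net = self.models_["3d"]
            stride = 2 ** (self.unet3d_depth - 1)
            img, _, _, unpad = volume_sample(prep, stride)
            logits = net.forward(img, train=False)
            prob = softmax(logits)[0, 1][unpad].astype(np.float32)
            full = uncrop(ImageVolume(prob, prep.voxel_size), prep.crop_record)
            rec = prep.crop_record
            wm = build_wm_mask(
                LabelVolume(uncrop(prep.csf, rec).data, prep.voxel_size),
                LabelVolume(uncrop(prep.brain, rec).data, prep.voxel_size),
                ventricle_mask=LabelVolume(uncrop(prep.ventricle, rec).data, prep.voxel_size),
                dilation_radius_mm=self.dilation_radius_mm,
                voxel_size=prep.voxel_size,
            )
            binary = postprocess(full, wm, self.threshold)
            return EnsembleOutput({"3d": full}, full, wm, binary)
        sizes = {p: self._plane_size(p) for p in self.models_}
        return predict_case(
            self.models_,
            prep,
            plane_sizes=sizes,
            threshold=self.threshold,
            dilation_radius_mm=self.dilation_radius_mm,
            batch_size=self.batch_size,
        )

    def predict_proba(self, X) -> list[EnsembleOutput]:
        """Ensemble outputs (per-plane and averaged probability maps)."""
        self._check_fitted()
        return [self._predict_prep(p) for p in self._prepare(X)]

    def predict(self, X) -> list[LabelVolume]:
        """Final binary lesion masks at the original volume dimensions."""
        return [out.binary for out in self.predict_proba(X)]

    def evaluate(self, X, y=None) -> list[MetricsReport]:
        """Full metrics report per case, with periventricular/deep split."""
        self._check_fitted()
        reports = []
        for i, (case, out) in enumerate(zip(X, self.predict_proba(X))):
            truth = y[i] if y is not None else case.wmh_truth
            reports.append(
                evaluate_case(
                    out.binary,
                    truth,
                    case.brain_mask,
                    case.flair.voxel_size,
                    ventricle_mask=case.ventricle_mask,
                )
            )
        return reports

    def score(self, X, y=None) -> float:
        """Median whole-volume Dice similarity index over the cases."""
        self._check_fitted()
        sis = []
        for i, (case, pred) in enumerate(zip(X, self.predict(X))):
            truth = y[i] if y is not None else case.wmh_truth
            sis.append(dice_si(pred, truth))
        return float(np.median(sis))


    # ------------------------------------------------------------------
    def save(self, model_dir) -> None:
        """Save trained networks (.npz + JSON sidecars) and parameters."""
        self._check_fitted()
        from pathlib import Path
        import json

        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        params = self.get_params()
        if params.get("plane_sizes"):
            params["plane_sizes"] = {k: list(v) for k, v in params["plane_sizes"].items()}
        params["noise_var_range"] = list(params["noise_var_range"])
        params["blur_sigma_range"] = list(params["blur_sigma_range"])
        (d / "params.json").write_text(json.dumps(params, indent=2))
        (d / "planes.json").write_text(json.dumps(sorted(self.models_)))
        for name, net in self.models_.items():
            net.save(d / f"{name}.npz")

    @classmethod
    def load(cls, model_dir) -> "WMHSegmenter":
        from pathlib import Path
        import json

        d = Path(model_dir)
        params = json.loads((d / "params.json").read_text())
        if params.get("plane_sizes"):
            params["plane_sizes"] = {
                k: tuple(v) for k, v in params["plane_sizes"].items()
            }
        params["noise_var_range"] = tuple(params["noise_var_range"])
        params["blur_sigma_range"] = tuple(params["blur_sigma_range"])
        est = cls(**params)
        est.models_ = {}
        est.history_ = {}
        for name in json.loads((d / "planes.json").read_text()):
            est.models_[name] = UNet.load(d / f"{name}.npz")
        est.n_parameters_ = sum(n.n_parameters() for n in est.models_.values())
        return est


def _cfg_dict(cfg: TrainConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def _with_truth(case, truth):
    from dataclasses import replace

    return replace(case, wmh_truth=truth)
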
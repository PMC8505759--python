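"""Synthetic brain phantoms with FLAIR/T1 contrast and ground-truth masks.

The phantom is an analytic geometry stand-in for a preprocessed (brain
extracted, bias corrected, co-registered) MRI pair: an ellipsoidal brain
with an outer cortical-CSF shell, a grey-matter ribbon beneath it, a white
matter interior and a central ventricle cavity.  Periventricular lesions are
bright, larger and confluent, placed adjoining the ventricle surface; deep
lesions are small punctate spheres in mid white matter, more than 10 mm from
the ventricles.  Lesions are hyperintense on FLAIR and hypointense on T1
relative to white matter.  Gaussian noise is added inside the brain.

Generation is a pure function of the spec (identical seed and spec give
bit-identical phantoms), which makes every downstream stage testable without
any image download.  Realistic MR physics (bias fields, motion, partial
volume) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .imageio import ImageVolume, LabelVolume, load_case, save_volume
from .weightmaps import distance_from_mask

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_cohort",
    "write_case",
    "read_case",
    "DEFAULT_CONTRAST",
]

#: tissue class -> (FLAIR mean, T1 mean), arbitrary units.  CSF is dark on
#: FLAIR (fluid suppressed) and T1; lesions are brighter than WM on FLAIR and
#: darker than WM on T1, with deep lesions at lower FLAIR contrast than
#: periventricular ones.
DEFAULT_CONTRAST: dict[str, tuple[float, float]] = {
    "csf": (0.15, 0.20),
    "gm": (0.55, 0.50),
    "wm": (0.45, 0.75),
    "ventricle": (0.15, 0.20),
    "pv_lesion": (0.90, 0.50),
    "deep_lesion": (0.80, 0.55),
}

#: distance (mm) from the ventricles separating periventricular from deep
DEEP_DISTANCE_MM = 10.0


class PhantomGeometryError(RuntimeError):
    """Requested lesions cannot be placed without violating the geometry."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults emulate an anisotropic axial acquisition (1 x 1 x 3 mm voxels)
    with a mixed lesion load: a couple of confluent periventricular lesions
    and a few punctate deep ones.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_pv_lesions: int = 2
    n_deep_lesions: int = 3
    pv_radius_range: tuple[float, float] = (4.0, 7.0)
    deep_radius_range: tuple[float, float] = (2.0, 3.5)
    noise_sigma: float = 0.05
    contrast: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_pv_lesions < 0 or self.n_deep_lesions < 0:
            raise ValueError("lesion counts must be >= 0")
        for name, rng_ in (("pv", self.pv_radius_range), ("deep", self.deep_radius_range)):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"{name}_radius_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomCase:
    """One generated case: image pair, anatomy masks and lesion truth."""

    flair: ImageVolume
    t1: ImageVolume
    brain_mask: LabelVolume
    ventricle_mask: LabelVolume
    gm_mask: LabelVolume
    csf_mask: LabelVolume
    wmh_truth: LabelVolume
    pv_truth: LabelVolume
    deep_truth: LabelVolume

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.flair.voxel_size


def _ellipsoid(coords_mm: list[np.ndarray], centre: np.ndarray, semi: np.ndarray) -> np.ndarray:
    r2 = sum(((c - mu) / s) ** 2 for c, mu, s in zip(coords_mm, centre, semi))
    return r2 <= 1.0


def _sphere(coords_mm: list[np.ndarray], centre_mm: np.ndarray, radius: float) -> np.ndarray:
    r2 = sum((c - mu) ** 2 for c, mu in zip(coords_mm, centre_mm))
    return r2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case from a spec (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    vox = np.asarray(spec.voxel_size, dtype=np.float64)
    extent = np.asarray(shape) * vox
    centre = extent / 2.0
    # voxel-centre physical coordinates, broadcastable per axis
    coords = [
        (np.arange(shape[a]) + 0.5).reshape([-1 if i == a else 1 for i in range(3)]) * vox[a]
        for a in range(3)
    ]

    brain_semi = 0.45 * extent
    brain = _ellipsoid(coords, centre, brain_semi)
    csf_inner = _ellipsoid(coords, centre, brain_semi - 2.0)
    gm_inner = _ellipsoid(coords, centre, brain_semi - 5.0)
    csf = brain & ~csf_inner
    gm = csf_inner & ~gm_inner
    interior = gm_inner

    vent_semi = np.minimum(np.array([7.0, 9.0, 7.0]), 0.3 * brain_semi)
    vent = _ellipsoid(coords, centre, vent_semi) & interior
    wm = interior & ~vent
    if not vent.any() or not gm.any():
        raise PhantomGeometryError("grid too small for ventricle/GM structures")

    d_vent = distance_from_mask(vent, tuple(vox))

    def _place(n: int, radius_range: tuple[float, float], deep: bool) -> np.ndarray:
        placed = np.zeros(shape, dtype=bool)
        if n == 0:
            return placed
        for _ in range(n):
            for attempt in range(spec.max_attempts):
                radius = rng.uniform(*radius_range)
                if deep:
                    # centre far enough that the whole sphere stays beyond the
                    # 10 mm shell; mild clipping at the outer WM edge only
                    cand = wm & (d_vent > DEEP_DISTANCE_MM + radius)
                else:
                    cand = wm & (d_vent > 0) & (d_vent <= 3.0)
                cand_idx = np.argwhere(cand)
                if cand_idx.size == 0:
                    continue
                c = cand_idx[rng.integers(len(cand_idx))]
                centre_mm = (c + 0.5) * vox
                sphere = _sphere(coords, centre_mm, radius)
                les = sphere & wm
                if deep:
                    les &= d_vent > DEEP_DISTANCE_MM
                    if not les.any() or les.sum() < 0.7 * sphere.sum():
                        continue
                    cm = np.argwhere(les).mean(axis=0)
                    cm_dist = d_vent[tuple(np.round(cm).astype(int))]
                    if cm_dist <= DEEP_DISTANCE_MM:
                        continue
                else:
                    # must adjoin the ventricle surface (within ~1 voxel of it)
                    if not les.any() or d_vent[les].min() > float(vox.max()):
                        continue
                placed |= les
                break
            else:
                raise PhantomGeometryError(
                    f"could not place a {'deep' if deep else 'periventricular'} lesion "
                    f"in {spec.max_attempts} attempts (infeasible geometry)"
                )
        return placed

    pv = _place(spec.n_pv_lesions, spec.pv_radius_range, deep=False)
    deep_les = _place(spec.n_deep_lesions, spec.deep_radius_range, deep=True)
    deep_les &= ~pv
    truth = pv | deep_les

    contrast = spec.contrast
    flair = np.zeros(shape, dtype=np.float32)
    t1 = np.zeros(shape, dtype=np.float32)
    for tissue, region in (
        ("csf", csf),
        ("gm", gm),
        ("wm", wm),
        ("ventricle", vent),
        ("pv_lesion", pv),
        ("deep_lesion", deep_les),
    ):
        f_mean, t_mean = contrast[tissue]
        flair[region] = f_mean
        t1[region] = t_mean

    if spec.noise_sigma > 0:
        noise_f = rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
        noise_t = rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
        flair[brain] += noise_f[brain]
        t1[brain] += noise_t[brain]

    vs = tuple(float(v) for v in vox)
    return PhantomCase(
        flair=ImageVolume(flair, vs),
        t1=ImageVolume(t1, vs),
        brain_mask=LabelVolume(brain, vs),
        ventricle_mask=LabelVolume(vent, vs),
        gm_mask=LabelVolume(gm, vs),
        csf_mask=LabelVolume(csf, vs),
        wmh_truth=LabelVolume(truth, vs),
        pv_truth=LabelVolume(pv, vs),
        deep_truth=LabelVolume(deep_les, vs),
    )


def generate_cohort(n: int, base_spec: PhantomSpec | None = None, seed: int = 0) -> list[PhantomCase]:
    """Generate ``n`` cases with jittered lesion counts and sizes.

    Per-case seeds and jitters derive deterministically from the cohort seed,
    so the cohort spans low to high lesion loads reproducibly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        # jitter counts around the base; a zero base stays zero (the spec
        # author asked for none of that lesion type)
        n_pv = max(0, base.n_pv_lesions + int(rng.integers(-1, 2))) if base.n_pv_lesions else 0
        n_deep = max(0, base.n_deep_lesions + int(rng.integers(-2, 3))) if base.n_deep_lesions else 0
        if n_pv == 0 and n_deep == 0 and base.n_pv_lesions + base.n_deep_lesions > 0:
            n_pv = 1
        scale = float(rng.uniform(0.75, 1.25))
        case_spec = replace(
            base,
            n_pv_lesions=n_pv,
            n_deep_lesions=n_deep,
            pv_radius_range=tuple(r * scale for r in base.pv_radius_range),
            deep_radius_range=tuple(r * scale for r in base.deep_radius_range),
            seed=int(rng.integers(2**31)),
        )
        cases.append(generate_phantom(case_spec))
    return cases


_CASE_FILES = {
    "flair": "FLAIR.nii.gz",
    "t1": "T1.nii.gz",
    "brain_mask": "brainmask.nii.gz",
    "ventricle_mask": "ventmask.nii.gz",
    "gm_mask": "gmmask.nii.gz",
    "csf_mask": "csfmask.nii.gz",
    "wmh_truth": "truth.nii.gz",
}


def write_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write a case's volumes as NIfTI files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _CASE_FILES.items():
        save_volume(getattr(case, attr), out / fname)


def read_case(case_dir: str | Path) -> PhantomCase:
    """Read a case written by :func:`write_case` (lesion split recomputed)."""
    d = Path(case_dir)
    flair, t1, masks = load_case(
        d / _CASE_FILES["flair"],
        d / _CASE_FILES["t1"],
        {
            "brain": d / _CASE_FILES["brain_mask"],
            "ventricle": d / _CASE_FILES["ventricle_mask"],
            "gm": d / _CASE_FILES["gm_mask"],
            "csf": d / _CASE_FILES["csf_mask"],
            "truth": d / _CASE_FILES["wmh_truth"],
        },
    )
    truth = masks["truth"]
    d_vent = distance_from_mask(masks["ventricle"], flair.voxel_size)
    pv = truth.as_bool() & (d_vent < DEEP_DISTANCE_MM)
    deep = truth.as_bool() & (d_vent >= DEEP_DISTANCE_MM)
    vs = flair.voxel_size
    return PhantomCase(
        flair=flair,
        t1=t1,
        brain_mask=masks["brain"],
        ventricle_mask=masks["ventricle"],
        gm_mask=masks["gm"],
        csf_mask=masks["csf"],
        wmh_truth=truth,
        pv_truth=LabelVolume(pv, vs),
        deep_truth=LabelVolume(deep, vs),
    )
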
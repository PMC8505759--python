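"""I/O, cropping, normalisation and slice-stack geometry round trips."""

import numpy as np
import pytest

from truenet.imageio import (
    ImageVolume,
    LabelVolume,
    crop_to_brain,
    gaussian_normalise,
    load_case,
    save_volume,
    uncrop,
)
from truenet.planes import (
    DEFAULT_PLANE_SIZES,
    extract_plane_slices,
    reassemble_probabilities,
    slice_single_volume,
)


# ---------------------------------------------------------------- I/O
def test_nifti_round_trip(tmp_path, default_case):
    save_volume(default_case.flair, tmp_path / "f.nii.gz")
    save_volume(default_case.t1, tmp_path / "t.nii.gz")
    save_volume(default_case.brain_mask, tmp_path / "b.nii.gz")
    fl, t1, masks = load_case(
        tmp_path / "f.nii.gz", tmp_path / "t.nii.gz", {"brain": tmp_path / "b.nii.gz"}
    )
    assert np.allclose(fl.data, default_case.flair.data, atol=1e-6)
    assert fl.voxel_size == default_case.flair.voxel_size
    assert np.array_equal(masks["brain"].data, default_case.brain_mask.data)


def test_load_case_rejects_shape_mismatch(tmp_path):
    save_volume(ImageVolume(np.zeros((16, 16, 16))), tmp_path / "f.nii.gz")
    save_volume(ImageVolume(np.zeros((16, 16, 17))), tmp_path / "t.nii.gz")
    with pytest.raises(ValueError, match="t.nii"):
        load_case(tmp_path / "f.nii.gz", tmp_path / "t.nii.gz")


def test_mask_binarised_at_half():
    lab = LabelVolume(np.array([[[0.0, 0.2], [0.5, 1.0000001]]] * 2))
    assert set(np.unique(lab.data)) <= {0, 1}
    assert lab.data[0, 1, 0] == 1 and lab.data[0, 0, 1] == 0


# ---------------------------------------------------------------- crop
def test_crop_identity_for_full_mask():
    vol = ImageVolume(np.random.default_rng(0).normal(size=(10, 11, 12)))
    mask = LabelVolume(np.ones((10, 11, 12)))
    out, rec = crop_to_brain(vol, mask, pad=0)
    assert out.data.shape == vol.data.shape
    assert np.array_equal(out.data, vol.data)


def test_crop_single_voxel_with_pad():
    mask = np.zeros((12, 12, 12))
    mask[5, 5, 5] = 1
    vol = ImageVolume(np.arange(12**3, dtype=float).reshape(12, 12, 12))
    out, rec = crop_to_brain(vol, LabelVolume(mask), pad=2)
    assert out.data.shape == (5, 5, 5)
    assert rec.start == (3, 3, 3)


def test_uncrop_inverts_crop(default_case):
    vol = default_case.flair
    out, rec = crop_to_brain(vol, default_case.brain_mask, pad=1)
    restored = uncrop(out, rec)
    assert restored.data.shape == vol.data.shape
    assert np.array_equal(restored.data[rec.slices], vol.data[rec.slices])
    outside = np.ones(vol.data.shape, dtype=bool)
    outside[rec.slices] = False
    assert np.all(restored.data[outside] == 0)


def test_crop_empty_mask_errors():
    vol = ImageVolume(np.zeros((16, 16, 16)))
    with pytest.raises(ValueError):
        crop_to_brain(vol, LabelVolume(np.zeros((16, 16, 16))))


# ------------------------------------------------------- normalisation
def test_gaussian_normalise_moments(rng):
    data = rng.normal(100.0, 5.0, size=(20, 20, 20))
    mask = np.zeros((20, 20, 20))
    mask[4:16, 4:16, 4:16] = 1
    out = gaussian_normalise(ImageVolume(data), LabelVolume(mask))
    inside = out.data[mask.astype(bool)]
    assert abs(inside.mean()) < 1e-6
    assert abs(inside.std() - 1.0) < 1e-5
    assert np.all(out.data[~mask.astype(bool)] == 0)


def test_gaussian_normalise_idempotent(rng):
    data = rng.normal(size=(16, 16, 16))
    mask = LabelVolume(np.ones((16, 16, 16)))
    once = gaussian_normalise(ImageVolume(data), mask)
    twice = gaussian_normalise(once, mask)
    assert np.allclose(once.data, twice.data, atol=1e-5)


def test_gaussian_normalise_constant_errors():
    vol = ImageVolume(np.full((16, 16, 16), 3.0))
    with pytest.raises(ValueError):
        gaussian_normalise(vol, LabelVolume(np.ones((16, 16, 16))))


# ------------------------------------------------------- plane slices
def test_default_plane_sizes():
    assert DEFAULT_PLANE_SIZES == {
        "axial": (128, 192),
        "sagittal": (192, 120),
        "coronal": (128, 80),
    }


def test_axial_slices_equal_raw_when_sizes_match(rng):
    vol = rng.normal(size=(128, 192, 8)).astype(np.float32)
    stack = slice_single_volume(vol, "axial")
    assert stack.shape == (8, 128, 192)
    assert np.array_equal(stack, np.moveaxis(vol, 2, 0))


@pytest.mark.parametrize("plane", ["axial", "sagittal", "coronal"])
def test_extract_reassemble_identity_without_resize(plane, rng):
    # source in-plane dims equal the target: the round trip must be exact
    sizes = {"axial": (24, 32, 6), "sagittal": (6, 24, 32), "coronal": (24, 6, 32)}
    shape = sizes[plane]
    target = {"axial": (24, 32), "sagittal": (24, 32), "coronal": (24, 32)}[plane]
    vol = rng.random(shape).astype(np.float32)
    stack = slice_single_volume(vol, plane, target)
    back = reassemble_probabilities(stack, plane, shape)
    assert np.allclose(back, np.clip(vol, 0, 1), atol=1e-6)


def test_sagittal_resize_round_trip_smooth_field():
    # a smooth ramp survives the bilinear down/up round trip
    y, z = np.meshgrid(np.linspace(0, 1, 96), np.linspace(0, 1, 60), indexing="ij")
    smooth = (0.4 * y + 0.3 * z + 0.2 * np.sin(2 * np.pi * y) * 0.1).astype(np.float32)
    vol = np.repeat(smooth[None], 4, axis=0)  # (4, 96, 60) sagittal stacks
    stack = slice_single_volume(vol.transpose(1, 2, 0).transpose(2, 0, 1), "sagittal",
                                (192, 120))
    # undo: reassemble to the original source shape
    source_shape = (4, 96, 60)
    back = reassemble_probabilities(stack, "sagittal", source_shape)
    orig = np.clip(vol, 0, 1)
    assert np.abs(back - orig).max() < 0.1


def test_extract_plane_slices_shape_and_count(default_case):
    ss = extract_plane_slices(default_case.flair, default_case.t1, "coronal")
    assert ss.data.shape == (default_case.flair.shape[1], 2, 128, 80)
    assert ss.n_slices == default_case.flair.shape[1]


def test_reassemble_clips_and_pads():
    probs = np.full((6, 24, 32), 1.5, dtype=np.float32)
    out = reassemble_probabilities(probs, "axial", (20, 28, 6))
    assert out.shape == (20, 28, 6)
    assert out.max() <= 1.0 and out.min() >= 0.0
    assert np.all(out == 1.0)  # crop of an all-bright map stays bright


def test_reassemble_count_mismatch_errors():
    with pytest.raises(ValueError):
        reassemble_probabilities(np.zeros((5, 24, 32)), "axial", (24, 32, 6))
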
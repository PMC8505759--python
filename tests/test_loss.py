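"""Composite loss: reference-value checks, bounds, monotonicity, gradients."""

import numpy as np
import pytest

from truenet.loss import (
    LossBatch,
    dice_loss,
    one_hot,
    softmax,
    total_loss,
    total_loss_and_grad,
    weighted_ce,
)


def _batch(rng, shape=(2, 8, 8), lesion_p=0.2, dwei=None):
    labels = (rng.random(shape) < lesion_p).astype(np.uint8)
    logits = rng.normal(size=(shape[0], 2, *shape[1:])).astype(np.float32)
    p = softmax(logits)
    y = one_hot(labels)
    return LossBatch(p=p, y=y, dwei=dwei), logits, labels


def reference_cross_entropy(p, y):
    """Independent unweighted CE oracle (plain formula, float64)."""
    p = np.clip(p.astype(np.float64), 1e-7, 1.0)
    n_vox = y.shape[0] * int(np.prod(y.shape[2:]))
    return float(-(y * np.log(p)).sum() / n_vox)


def test_ce_zero_for_perfect_prediction():
    y = one_hot(np.ones((1, 4, 4), dtype=np.uint8))
    p = y.astype(np.float32)
    assert weighted_ce(LossBatch(p=p, y=y)) == pytest.approx(0.0, abs=1e-5)


def test_ce_single_voxel_weighted_value():
    # one voxel, lesion class, p=0.5, weight 2 -> contribution 2*ln 2
    y = one_hot(np.ones((1, 1, 1), dtype=np.uint8))
    p = np.full((1, 2, 1, 1), 0.5, dtype=np.float32)
    dwei = np.full((1, 1, 1), 2.0, dtype=np.float32)
    val = weighted_ce(LossBatch(p=p, y=y, dwei=dwei))
    assert val == pytest.approx(2 * np.log(2), abs=1e-6)
    assert val == pytest.approx(1.3863, abs=1e-3)


def test_ce_unit_weights_match_reference(rng):
    batch, _, _ = _batch(rng, dwei=np.ones((2, 8, 8), dtype=np.float32))
    assert weighted_ce(batch) == pytest.approx(
        reference_cross_entropy(batch.p, batch.y), abs=1e-6
    )


def test_dice_reference_values():
    m = np.zeros((1, 4, 4), dtype=np.uint8)
    m[0, :2, :2] = 1  # |M| = 4
    y = one_hot(m)
    pth_same = m[0].astype(float)[None]
    assert dice_loss(LossBatch(p=y.astype(np.float32), y=y, pth=pth_same),
                     mode="hard") == pytest.approx(-1.0)
    pth_disjoint = np.zeros((1, 4, 4))
    pth_disjoint[0, 2:, 2:] = 1
    assert dice_loss(LossBatch(p=y.astype(np.float32), y=y, pth=pth_disjoint),
                     mode="hard") == pytest.approx(0.0)
    pth_half = np.zeros((1, 4, 4))
    pth_half[0, 0, :2] = 1  # overlap 2
    pth_half[0, 3, :2] = 1  # |P| = 4
    assert dice_loss(LossBatch(p=y.astype(np.float32), y=y, pth=pth_half),
                     mode="hard") == pytest.approx(-2 * 2 / 8)


def test_dice_random_masks_match_formula(rng):
    for _ in range(100):
        m = (rng.random((1, 6, 6)) < 0.3).astype(np.uint8)
        pth = (rng.random((1, 6, 6)) < 0.3).astype(float)
        y = one_hot(m)
        got = dice_loss(LossBatch(p=y.astype(np.float32), y=y, pth=pth), mode="hard")
        inter = (m[0] * pth[0]).sum()
        denom = m.sum() + pth.sum()
        want = -1.0 if denom == 0 else -2.0 * inter / denom
        assert got == pytest.approx(want)
        assert -1.0 <= got <= 0.0


def test_dice_bounds_soft(rng):
    for _ in range(20):
        batch, _, _ = _batch(rng)
        val = dice_loss(batch, mode="soft")
        assert -1.0 <= val <= 0.0


def test_total_loss_is_sum_of_components(rng):
    dwei = np.ones((2, 8, 8), dtype=np.float32)
    batch, _, _ = _batch(rng, dwei=dwei)
    assert total_loss(batch) == pytest.approx(
        weighted_ce(batch) + dice_loss(batch, mode="soft"), abs=1e-9
    )
    assert total_loss(batch) >= -1.0


def test_perfect_prediction_total_loss_near_minus_one():
    labels = np.zeros((1, 6, 6), dtype=np.uint8)
    labels[0, 2:4, 2:4] = 1
    y = one_hot(labels)
    p = np.clip(y.astype(np.float32), 1e-6, 1 - 1e-6)
    p /= p.sum(axis=1, keepdims=True)
    batch = LossBatch(p=p, y=y)
    assert total_loss(batch) == pytest.approx(-1.0, abs=1e-3)


def test_loss_and_grad_value_matches_loss_functions(rng):
    dwei = rng.random((2, 8, 8)).astype(np.float32) * 3
    batch, logits, labels = _batch(rng, dwei=dwei)
    L, _ = total_loss_and_grad(logits, labels, dwei)
    want = weighted_ce(batch) + dice_loss(batch, mode="soft")
    assert L == pytest.approx(want, abs=1e-5)


def test_gradient_matches_finite_differences(rng):
    logits = rng.normal(size=(1, 2, 4, 4)).astype(np.float64)
    labels = (rng.random((1, 4, 4)) < 0.3).astype(np.uint8)
    dwei = rng.random((1, 4, 4)) * 2
    _, grad = total_loss_and_grad(logits.astype(np.float32), labels, dwei)
    eps = 1e-4
    for idx in [(0, 0, 1, 1), (0, 1, 2, 3), (0, 1, 0, 0)]:
        up, down = logits.copy(), logits.copy()
        up[idx] += eps
        down[idx] -= eps
        lu, _ = total_loss_and_grad(up.astype(np.float32), labels, dwei)
        ld, _ = total_loss_and_grad(down.astype(np.float32), labels, dwei)
        assert grad[idx] == pytest.approx((lu - ld) / (2 * eps), rel=5e-2, abs=1e-6)


def test_gradient_finite_and_nonzero(rng):
    _, logits, labels = _batch(rng)
    _, grad = total_loss_and_grad(logits, labels, None)
    assert np.all(np.isfinite(grad))
    assert np.abs(grad).max() > 0


def test_moving_towards_label_never_increases_loss(rng):
    logits = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
    labels = (rng.random((1, 4, 4)) < 0.4).astype(np.uint8)
    dwei = np.ones((1, 4, 4), dtype=np.float32)
    L0, _ = total_loss_and_grad(logits, labels, dwei)
    nudged = logits.copy()
    nudged[0, 1][labels[0] == 1] += 0.5  # push WMH logit toward WMH labels
    nudged[0, 0][labels[0] == 0] += 0.5
    L1, _ = total_loss_and_grad(nudged, labels, dwei)
    assert L1 <= L0 + 1e-9


def test_deep_upweighting_raises_false_negative_penalty():
    # same miss, higher weight -> strictly larger CE penalty
    labels = np.zeros((1, 4, 4), dtype=np.uint8)
    labels[0, 1, 1] = 1
    logits = np.zeros((1, 2, 4, 4), dtype=np.float32)  # p = 0.5 everywhere
    w_pv = np.ones((1, 4, 4), dtype=np.float32) * 5.0
    w_deep = np.ones((1, 4, 4), dtype=np.float32) * 25.0
    L_pv, _ = total_loss_and_grad(logits, labels, w_pv, variant="weighted_ce")
    L_deep, _ = total_loss_and_grad(logits, labels, w_deep, variant="weighted_ce")
    assert L_deep > L_pv


def test_variant_arms(rng):
    dwei = rng.random((2, 8, 8)).astype(np.float32) * 3 + 1
    batch, logits, labels = _batch(rng, dwei=dwei)
    ce_only, _ = total_loss_and_grad(logits, labels, dwei, variant="ce_only")
    assert ce_only == pytest.approx(reference_cross_entropy(batch.p, batch.y), abs=1e-6)
    wce, _ = total_loss_and_grad(logits, labels, dwei, variant="weighted_ce")
    assert wce == pytest.approx(weighted_ce(batch), abs=1e-6)
    dice, _ = total_loss_and_grad(logits, labels, dwei, variant="dice_only")
    assert dice == pytest.approx(dice_loss(batch, mode="soft"), abs=1e-6)
    with pytest.raises(ValueError):
        total_loss_and_grad(logits, labels, dwei, variant="focal")


def test_loss_batch_validation(rng):
    p = np.full((1, 2, 2, 2), 0.5, dtype=np.float32)
    y = one_hot(np.zeros((1, 2, 2), dtype=np.uint8))
    LossBatch(p=p, y=y)  # fine
    with pytest.raises(ValueError):
        LossBatch(p=p * 2, y=y)  # not a distribution
    with pytest.raises(ValueError):
        LossBatch(p=p, y=y, dwei=-np.ones((1, 2, 2)))
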
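"""Evaluation metrics against independent brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from truenet.metrics import (
    avd,
    cluster_metrics,
    dice_si,
    evaluate_case,
    hausdorff95,
    split_pwmh_dwmh,
    voxel_rates,
)


# ------------------------------------------------------------- oracles
def bfs_components(mask: np.ndarray) -> list[set]:
    """Flood-fill 26-connected components (independent of skimage)."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                nb = tuple(a + d for a, d in zip(v, off))
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(comp)
    return comps


def oracle_cluster_metrics(pred, manual):
    p_comps = bfs_components(pred)
    m_comps = bfs_components(manual)
    pred_set = set(map(tuple, np.argwhere(pred)))
    man_set = set(map(tuple, np.argwhere(manual)))
    tpr = sum(1 for c in m_comps if c & pred_set) / len(m_comps) if m_comps else None
    prec = sum(1 for c in p_comps if c & man_set) / len(p_comps) if p_comps else None
    f1 = None
    if tpr is not None and prec is not None:
        f1 = 2 * tpr * prec / (tpr + prec) if tpr + prec else 0.0
    return tpr, prec, f1


def oracle_boundary(mask):
    out = np.zeros_like(mask)
    for v in map(tuple, np.argwhere(mask)):
        for ax in range(3):
            for d in (-1, 1):
                nb = list(v)
                nb[ax] += d
                nb = tuple(nb)
                if not (0 <= nb[ax] < mask.shape[ax]) or not mask[nb]:
                    out[v] = True
    return out


def oracle_h95(pred, manual, voxel_size):
    bp = np.argwhere(oracle_boundary(pred)) * np.asarray(voxel_size)
    bm = np.argwhere(oracle_boundary(manual)) * np.asarray(voxel_size)
    d_pm = [np.sqrt(((bm - q) ** 2).sum(axis=1)).min() for q in bp]
    d_mp = [np.sqrt(((bp - q) ** 2).sum(axis=1)).min() for q in bm]
    return float(np.percentile(np.asarray(d_pm + d_mp), 95))


def random_pair(rng, shape=(12, 12, 12), p=0.08):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b


# ------------------------------------------------------------- dice/voxel
def test_dice_basic_cases(rng):
    shape = (10, 10, 10)
    a = np.zeros(shape, bool)
    a[2:4, 2:4, 2:4] = True
    assert dice_si(a, a) == 1.0
    assert dice_si(np.zeros(shape, bool), np.zeros(shape, bool)) == 1.0
    b = np.zeros(shape, bool)
    b[6:8, 6:8, 6:8] = True
    assert dice_si(a, b) == 0.0


def test_dice_known_overlap():
    manual = np.zeros((10, 10, 10), bool)
    manual.flat[:100] = True
    pred = np.zeros((10, 10, 10), bool)
    pred.flat[20:120] = True  # overlap 80
    assert dice_si(pred, manual) == pytest.approx(2 * 80 / 200)


def test_dice_symmetry(rng):
    a, b = random_pair(rng)
    assert dice_si(a, b) == dice_si(b, a)


def test_voxel_rates_counting():
    shape = (10, 10, 10)
    manual = np.zeros(shape, bool)
    manual.flat[:10] = True
    pred = np.zeros(shape, bool)
    pred.flat[2:15] = True  # hits 8 of 10 manual, 5 spurious
    brain = np.ones(shape, bool)
    tpr, fpr = voxel_rates(pred, manual, brain)
    assert tpr == pytest.approx(0.8)
    assert fpr == pytest.approx(5 / 990)


def test_voxel_rates_degenerate():
    shape = (6, 6, 6)
    zeros = np.zeros(shape, bool)
    brain = np.ones(shape, bool)
    manual = zeros.copy()
    manual[0, 0, 0] = True
    tpr, fpr = voxel_rates(zeros, manual, brain)
    assert tpr == 0.0 and fpr == 0.0
    tpr, _ = voxel_rates(zeros, zeros, brain)
    assert tpr is None


# ------------------------------------------------------------- clusters
def test_diagonal_voxels_one_cluster():
    m = np.zeros((4, 4, 4), bool)
    m[1, 1, 1] = True
    m[2, 2, 2] = True  # corner-touching: 26-connectivity joins them
    tpr, prec, f1 = cluster_metrics(m, m)
    assert (tpr, prec, f1) == (1.0, 1.0, 1.0)
    assert len(bfs_components(m)) == 1


def test_cluster_metrics_worked_example():
    # 3 true clusters, 2 detected; 4 predicted clusters, 2 overlapping truth
    manual = np.zeros((20, 8, 8), bool)
    pred = np.zeros((20, 8, 8), bool)
    for i, x in enumerate((1, 6, 11)):
        manual[x, 1:3, 1:3] = True
    pred[1, 1, 1] = True       # overlaps true cluster 1
    pred[6, 2, 2] = True       # overlaps true cluster 2
    pred[16, 1, 1] = True      # false positive
    pred[18, 5, 5] = True      # false positive
    tpr, prec, f1 = cluster_metrics(pred, manual)
    assert tpr == pytest.approx(2 / 3)
    assert prec == pytest.approx(1 / 2)
    assert f1 == pytest.approx(4 / 7)


def test_cluster_metrics_match_bfs_oracle(rng):
    for _ in range(25):
        pred, manual = random_pair(rng)
        got = cluster_metrics(pred, manual)
        want = oracle_cluster_metrics(pred, manual)
        for g, w in zip(got, want):
            if w is None:
                assert g is None
            else:
                assert g == pytest.approx(w)


# ------------------------------------------------------------- avd/h95
def test_avd_formula():
    shape = (10, 10, 10)
    manual = np.zeros(shape, bool)
    manual.flat[:100] = True
    pred = np.zeros(shape, bool)
    pred.flat[:150] = True
    assert avd(pred, manual, (1, 1, 1)) == pytest.approx(50.0)
    assert avd(manual, manual, (1, 1, 1)) == 0.0
    with pytest.raises(ValueError):
        avd(pred, np.zeros(shape, bool), (1, 1, 1))


def test_avd_volume_consistency():
    # a 25% AVD on a 2400 mm^3 lesion is a 600 mm^3 discrepancy
    voxel = (1.0, 1.0, 3.0)
    voxvol = 3.0
    manual = np.zeros((20, 20, 20), bool)
    manual.flat[: int(2400 / voxvol)] = True
    pred = np.zeros((20, 20, 20), bool)
    pred.flat[: int(3000 / voxvol)] = True  # 600 mm^3 larger
    assert avd(pred, manual, voxel) == pytest.approx(25.0)


def test_h95_identical_and_parallel_planes():
    m = np.zeros((10, 10, 10), bool)
    m[3, 2:8, 2:8] = True
    assert hausdorff95(m, m, (1, 1, 1)) == 0.0
    p = np.zeros((10, 10, 10), bool)
    p[7, 2:8, 2:8] = True  # 4 voxels away along x
    assert hausdorff95(p, m, (1, 1, 1)) == pytest.approx(4.0)


def test_h95_matches_brute_force(rng):
    for _ in range(15):
        pred, manual = random_pair(rng, p=0.15)
        if not pred.any() or not manual.any():
            continue
        got = hausdorff95(pred, manual, (1.0, 1.0, 2.0))
        want = oracle_h95(pred, manual, (1.0, 1.0, 2.0))
        assert got == pytest.approx(want, abs=1e-6)


def test_h95_symmetry_and_empty(rng):
    pred, manual = random_pair(rng, p=0.2)
    assert hausdorff95(pred, manual, (1, 1, 1)) == hausdorff95(manual, pred, (1, 1, 1))
    assert hausdorff95(np.zeros((6, 6, 6), bool), manual[:6, :6, :6], (1, 1, 1)) is None


# ------------------------------------------------------------- regional
def test_split_partition(default_case):
    case = default_case
    mask = case.wmh_truth.as_bool()
    pw, dw = split_pwmh_dwmh(mask, case.ventricle_mask, case.voxel_size)
    assert not (pw & dw).any()
    assert np.array_equal(pw | dw, mask)
    assert pw.sum() + dw.sum() == mask.sum()


def test_split_respects_10mm_rule(default_case):
    case = default_case
    pw, dw = split_pwmh_dwmh(case.wmh_truth, case.ventricle_mask, case.voxel_size)
    from truenet.weightmaps import distance_from_mask

    d = distance_from_mask(case.ventricle_mask, case.voxel_size)
    assert dw.sum() > 0 and pw.sum() > 0
    assert d[dw].min() >= 10.0
    assert d[pw].max() < 10.0


def test_lesion_next_to_ventricle_is_pwmh(default_case):
    case = default_case
    vent = case.ventricle_mask.as_bool()
    from scipy import ndimage

    shell = ndimage.binary_dilation(vent) & ~vent
    mask = np.zeros_like(vent)
    mask[tuple(np.argwhere(shell)[0])] = True
    pw, dw = split_pwmh_dwmh(mask, case.ventricle_mask, case.voxel_size)
    assert pw.sum() == 1 and dw.sum() == 0


def test_regional_tp_counts_recombine(default_case, rng):
    case = default_case
    manual = case.wmh_truth.as_bool()
    pred = manual & (rng.random(manual.shape) < 0.8)
    report = evaluate_case(pred, manual, case.brain_mask, case.voxel_size,
                           ventricle_mask=case.ventricle_mask)
    tp_whole = (pred & manual).sum()
    tp_regions = 0
    from truenet.weightmaps import distance_from_mask

    d = distance_from_mask(case.ventricle_mask, case.voxel_size)
    for name, region in (("pwmh", d < 10), ("dwmh", d >= 10)):
        sub = report.per_region[name]
        tp_regions += round(sub.tpr_voxel * (manual & region).sum()) if sub.tpr_voxel else 0
    assert tp_regions == tp_whole


def test_evaluate_case_report_fields(default_case):
    case = default_case
    report = evaluate_case(
        case.wmh_truth, case.wmh_truth, case.brain_mask, case.voxel_size,
        ventricle_mask=case.ventricle_mask,
    )
    assert report.si == 1.0
    assert report.tpr_voxel == 1.0 and report.fpr_voxel == 0.0
    assert report.f1_cluster == 1.0
    assert report.avd_percent == 0.0
    assert report.h95 == 0.0
    assert set(report.per_region) == {"pwmh", "dwmh"}
    assert report.volume_manual_mm3 == report.volume_pred_mm3 > 0
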
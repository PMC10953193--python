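"""Anchor enumeration, IoU geometry, assignment rules and box coding."""

import numpy as np
import pytest

from noduledet.anchors import (ANCHOR_SIZES, GroundTruthBox, IGNORE, NEGATIVE,
                               POSITIVE, assign_iou, assign_nearest,
                               decode_prediction, encode_targets,
                               enumerate_anchors, iou_cube)


def brute_force_nearest_labels(anchors, gts):
    """Independent oracle: score every (anchor, gt) pair with python tuples."""
    pos = {}
    taken = set()
    for j, gt in enumerate(gts):
        best_key, best_k = None, None
        for k in range(len(anchors)):
            if k in taken:
                continue
            p = anchors.points[k]
            d2 = sum((p[i] - gt.center[i]) ** 2 for i in range(3))
            key = (d2, p[0], p[1], p[2],
                   abs(anchors.sizes[k] - gt.diameter), anchors.sizes[k])
            if best_key is None or key < best_key:
                best_key, best_k = key, k
        taken.add(best_k)
        pos[best_k] = j
    return pos


def voxelized_iou(center_a, size_a, center_b, size_b, resolution=4):
    """Independent oracle: count sub-voxel samples inside each cube."""
    lo = np.minimum(np.asarray(center_a) - size_a, np.asarray(center_b) - size_b)
    hi = np.maximum(np.asarray(center_a) + size_a, np.asarray(center_b) + size_b)
    axes = [np.arange(l, h, 1.0 / resolution) + 0.5 / resolution
            for l, h in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)

    def inside(c, s):
        return ((np.abs(zz - c[0]) < s / 2) & (np.abs(yy - c[1]) < s / 2)
                & (np.abs(xx - c[2]) < s / 2))

    in_a, in_b = inside(center_a, size_a), inside(center_b, size_b)
    union = np.count_nonzero(in_a | in_b)
    return np.count_nonzero(in_a & in_b) / union if union else 0.0


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def test_enumeration_count_and_order():
    grid = enumerate_anchors([(4, 4, 4)], [2])
    assert len(grid) == 4 ** 3 * 3
    # sizes cycle fastest, ascending
    np.testing.assert_array_equal(grid.sizes[:6], [5, 10, 20, 5, 10, 20])
    # grid index (1,1,1) at stride 2 with center offset -> point (3,3,3)
    idx = (((1 * 4) + 1) * 4 + 1) * 3
    np.testing.assert_array_equal(grid.points[idx], [3.0, 3.0, 3.0])


def test_enumeration_is_deterministic_and_level_major():
    shapes, strides = [(4, 4, 4), (2, 2, 2)], [2, 4]
    a = enumerate_anchors(shapes, strides)
    b = enumerate_anchors(shapes, strides)
    np.testing.assert_array_equal(a.points, b.points)
    np.testing.assert_array_equal(a.levels, np.repeat([0, 1], [192, 24]))


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_cube_examples():
    assert iou_cube((0, 0, 0), 4.0, (0, 0, 0), 4.0) == pytest.approx(1.0)
    assert iou_cube((0, 0, 0), 2.0, (10, 0, 0), 2.0) == 0.0
    # size-2 cubes offset by 1 along one axis: inter 4, union 12
    assert iou_cube((0, 0, 0), 2.0, (1, 0, 0), 2.0) == pytest.approx(1 / 3)


def test_iou_cube_symmetric_and_matches_voxelized_oracle(rng):
    for _ in range(20):
        ca = rng.integers(0, 8, size=3).astype(float)
        cb = rng.integers(0, 8, size=3).astype(float)
        sa, sb = rng.integers(2, 7, size=2).astype(float)
        got = iou_cube(ca, sa, cb, sb)
        assert got == pytest.approx(iou_cube(cb, sb, ca, sa))
        assert got == pytest.approx(voxelized_iou(ca, sa, cb, sb), abs=0.02)


# ---------------------------------------------------------------------------
# IoU assignment
# ---------------------------------------------------------------------------

def test_assign_iou_exact_coincidence_is_positive():
    grid = enumerate_anchors([(8, 8, 8)], [2])
    gt = GroundTruthBox((5.0, 5.0, 5.0), 10.0)   # sits on an anchor point
    res = assign_iou(grid, [gt], 0.5, 0.3)
    k = np.nonzero(res.labels == POSITIVE)[0]
    assert (grid.sizes[k] == 10.0).any()


def test_assign_iou_can_produce_multiple_positives():
    """Adjacent stride-2 anchors both clear the threshold on one ground truth
    (the multi-positive behaviour that motivates nearest-anchor assignment)."""
    grid = enumerate_anchors([(8, 8, 8)], [2])
    gt = GroundTruthBox((6.0, 5.0, 5.0), 10.0)   # midway between two points
    iou_a = iou_cube((5.0, 5.0, 5.0), 10.0, gt.center, gt.diameter)
    iou_b = iou_cube((7.0, 5.0, 5.0), 10.0, gt.center, gt.diameter)
    assert min(iou_a, iou_b) >= 0.3
    res = assign_iou(grid, [gt], pos_threshold=0.3, neg_threshold=0.1)
    assert res.n_positive >= 2


def test_assign_iou_empty_gts_all_negative():
    grid = enumerate_anchors([(4, 4, 4)], [2])
    res = assign_iou(grid, [])
    assert res.n_positive == 0
    assert np.all(res.labels == NEGATIVE)


def test_assign_iou_forces_positive_for_unmatched_gt():
    grid = enumerate_anchors([(4, 4, 4)], [2])
    res = assign_iou(grid, [GroundTruthBox((3.0, 3.0, 3.0), 2.0)],
                     pos_threshold=0.9, neg_threshold=0.3)
    assert res.n_positive == 1   # no anchor reaches IoU 0.9; best is forced


# ---------------------------------------------------------------------------
# Nearest-anchor assignment
# ---------------------------------------------------------------------------

def test_assign_nearest_picks_closest_point_then_closest_size():
    grid = enumerate_anchors([(16, 16, 16)], [1])
    gt = GroundTruthBox((10.2, 10.4, 10.1), 6.0)
    res = assign_nearest(grid, [gt])
    k = int(np.nonzero(res.labels == POSITIVE)[0][0])
    # stride-1 cell centers sit at half-integers; (10.5, 10.5, 10.5) is nearest
    np.testing.assert_array_equal(grid.points[k], [10.5, 10.5, 10.5])
    assert grid.sizes[k] == 5.0     # |5-6| < |10-6| < |20-6|
    assert res.n_positive == 1


def test_assign_nearest_two_distant_gts_two_positives():
    grid = enumerate_anchors([(32, 32, 32)], [2])
    gts = [GroundTruthBox((10.0, 10.0, 10.0), 8.0),
           GroundTruthBox((50.0, 50.0, 50.0), 8.0)]
    res = assign_nearest(grid, gts)
    assert res.n_positive == 2
    pos = np.nonzero(res.labels == POSITIVE)[0]
    assert set(res.matched_gt[pos]) == {0, 1}


def test_assign_nearest_empty_gts_all_negative():
    grid = enumerate_anchors([(4, 4, 4)], [2])
    res = assign_nearest(grid, [])
    assert np.all(res.labels == NEGATIVE)


def test_assign_nearest_size_tie_prefers_smaller():
    # diameter 7.5 is equidistant from sizes 5 and 10
    grid = enumerate_anchors([(8, 8, 8)], [2])
    res = assign_nearest(grid, [GroundTruthBox((5.0, 5.0, 5.0), 7.5)])
    k = int(np.nonzero(res.labels == POSITIVE)[0][0])
    assert grid.sizes[k] == 5.0


def test_assign_nearest_matches_bruteforce_on_random_instances(rng):
    for _ in range(30):
        shape = tuple(rng.integers(2, 9, size=3))
        stride = int(rng.choice([1, 2, 4]))
        grid = enumerate_anchors([shape], [stride])
        n_gts = int(rng.integers(1, 5))
        extent = np.asarray(shape) * stride
        gts = [GroundTruthBox(tuple(rng.uniform(0, extent)),
                              float(rng.uniform(1, 25))) for _ in range(n_gts)]
        res = assign_nearest(grid, gts)
        oracle = brute_force_nearest_labels(grid, gts)
        got = {int(k): int(res.matched_gt[k])
               for k in np.nonzero(res.labels == POSITIVE)[0]}
        assert got == oracle


def test_iou_positive_count_at_least_nearest_positive_count(rng):
    """IoU matching hands out at least as many positives as nearest-anchor."""
    for _ in range(10):
        grid = enumerate_anchors([(8, 8, 8)], [2])
        gts = [GroundTruthBox(tuple(rng.uniform(2, 14, size=3)),
                              float(rng.uniform(4, 20)))
               for _ in range(int(rng.integers(1, 4)))]
        n_iou = assign_iou(grid, gts, pos_threshold=0.3, neg_threshold=0.1).n_positive
        n_near = assign_nearest(grid, gts).n_positive
        assert n_iou >= n_near
        assert n_near == len(gts)


def test_nearest_ignore_rule_marks_near_hits():
    grid = enumerate_anchors([(8, 8, 8)], [2])
    res = assign_nearest(grid, [GroundTruthBox((7.0, 7.0, 7.0), 10.0)])
    assert (res.labels == IGNORE).sum() > 0
    assert res.n_positive == 1


# ---------------------------------------------------------------------------
# Box coding
# ---------------------------------------------------------------------------

def test_encode_identity_and_log_ratio():
    gt = GroundTruthBox((3.0, 3.0, 3.0), 10.0)
    np.testing.assert_allclose(
        encode_targets(np.array([3.0, 3.0, 3.0]), 10.0, gt), [0, 0, 0, 0], atol=1e-7)
    enc = encode_targets(np.array([3.0, 3.0, 3.0]), 10.0,
                         GroundTruthBox((3.0, 3.0, 3.0), 20.0))
    assert enc[3] == pytest.approx(np.log(2.0), abs=1e-6)


def test_decode_zero_regression_returns_anchor():
    center, diam = decode_prediction(np.array([4.0, 6.0, 8.0]), 10.0, [0, 0, 0, 0])
    np.testing.assert_array_equal(center, [4.0, 6.0, 8.0])
    assert diam == 10.0
    _, d2 = decode_prediction(np.array([0, 0, 0]), 20.0, [0, 0, 0, -np.log(2.0)])
    assert d2 == pytest.approx(10.0)


def test_decode_inverts_encode(rng):
    for _ in range(50):
        point = rng.uniform(0, 60, size=3)
        size = float(rng.choice(ANCHOR_SIZES))
        gt = GroundTruthBox(tuple(rng.uniform(0, 60, size=3)),
                            float(rng.uniform(3, 30)))
        center, diam = decode_prediction(point, size,
                                         encode_targets(point, size, gt))
        np.testing.assert_allclose(center, gt.center, atol=1e-5)
        assert diam == pytest.approx(gt.diameter, abs=1e-5)


def test_encode_rejects_nonpositive_diameter():
    with pytest.raises(ValueError):
        GroundTruthBox((0, 0, 0), 0.0)
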
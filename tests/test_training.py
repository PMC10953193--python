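"""Detection loss, augmentation and the training loop."""

import numpy as np
import pytest

from noduledet.anchors import (AssignmentResult, GroundTruthBox, IGNORE,
                               NEGATIVE, POSITIVE, assign_nearest,
                               enumerate_anchors, encode_targets)
from noduledet.model import HeadOutput, ModelConfig, build_model
from noduledet.training import (AugmentConfig, AugmentParams, TrainConfig,
                                apply_augmentation, augment, detection_loss,
                                train)
from noduledet.volume import Patch


def single_level_output(logits, regs):
    """HeadOutput with one 1x1x1-cell level holding 3 anchors."""
    cls = np.asarray(logits, dtype=np.float32).reshape(3, 1, 1, 1)
    reg = np.asarray(regs, dtype=np.float32).reshape(3, 4, 1, 1, 1)
    return HeadOutput([cls], [reg])


def assignment(labels, targets=None):
    labels = np.asarray(labels, dtype=np.int8)
    t = np.zeros((len(labels), 4), dtype=np.float32)
    if targets is not None:
        t[:] = targets
    matched = np.where(labels == POSITIVE, 0, -1).astype(np.int32)
    return AssignmentResult(labels, matched, t)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def test_focal_loss_closed_form_single_positive():
    logit = 0.3
    p = 1.0 / (1.0 + np.exp(-logit))
    out = single_level_output([logit, -30.0, -30.0], np.zeros((3, 4)))
    asg = assignment([POSITIVE, NEGATIVE, NEGATIVE])
    total, cls, reg = detection_loss(out, asg, focal_alpha=0.25, focal_gamma=2.0)
    expected = -0.25 * (1 - p) ** 2 * np.log(p)
    assert cls == pytest.approx(expected, rel=1e-5)
    assert reg == pytest.approx(0.0, abs=1e-6)


def test_ignored_anchor_logits_do_not_affect_loss():
    out_a = single_level_output([2.0, -7.0, 0.0], np.zeros((3, 4)))
    out_b = single_level_output([2.0, -7.0, 123.0], np.zeros((3, 4)))
    asg = assignment([POSITIVE, NEGATIVE, IGNORE])
    assert detection_loss(out_a, asg)[0] == pytest.approx(
        detection_loss(out_b, asg)[0], rel=1e-12)


def test_perfect_predictions_give_negligible_loss():
    target = np.array([0.2, -0.1, 0.05, 0.3], dtype=np.float32)
    regs = np.zeros((3, 4), dtype=np.float32)
    regs[0] = target
    out = single_level_output([20.0, -20.0, -20.0], regs)
    asg = assignment([POSITIVE, NEGATIVE, NEGATIVE], targets=0)
    asg.targets[0] = target
    total, _, _ = detection_loss(out, asg)
    assert total < 1e-3


def test_zero_positives_still_defined():
    out = single_level_output([0.0, 0.0, 0.0], np.ones((3, 4)))
    asg = assignment([NEGATIVE, NEGATIVE, NEGATIVE])
    total, cls, reg = detection_loss(out, asg)
    assert reg == 0.0
    assert np.isfinite(total) and cls > 0


def test_loss_gradients_match_numerical(rng):
    logits = rng.normal(0, 2, size=3)
    regs = rng.normal(0, 1, size=(3, 4))
    asg = assignment([POSITIVE, NEGATIVE, IGNORE])
    asg.targets[0] = rng.normal(0, 1, size=4)
    out = single_level_output(logits, regs)
    _, _, _, (dc, dr) = detection_loss(out, asg, with_grads=True)
    eps = 1e-3   # inputs are stored in float32; a larger step beats rounding
    for i in range(3):
        pert = logits.copy()
        pert[i] += eps
        up = detection_loss(single_level_output(pert, regs), asg)[0]
        pert[i] -= 2 * eps
        dn = detection_loss(single_level_output(pert, regs), asg)[0]
        assert dc[0][i, 0, 0, 0] == pytest.approx((up - dn) / (2 * eps), rel=1e-2,
                                                  abs=1e-4)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_identity_augmentation_is_noop(rng):
    patch = rng.random((16, 16, 16)).astype(np.float32)
    nodules = [(np.array([8.0, 5.0, 9.0]), 6.0, 0.5)]
    out, nods = apply_augmentation(patch, nodules, AugmentParams())
    np.testing.assert_array_equal(out, patch)
    assert len(nods) == 1


def test_augment_deterministic_given_seed(rng):
    patch = rng.random((16, 16, 16)).astype(np.float32)
    nodules = [(np.array([8.0, 8.0, 8.0]), 5.0, None)]
    a_patch, a_nod = augment(patch, nodules, AugmentConfig(), seed=9)
    b_patch, b_nod = augment(patch, nodules, AugmentConfig(), seed=9)
    np.testing.assert_array_equal(a_patch, b_patch)
    np.testing.assert_array_equal(a_nod[0][0], b_nod[0][0])


def test_scaling_multiplies_diameter_and_scales_center_about_patch_center():
    patch = np.zeros((17, 17, 17), dtype=np.float32)
    center = np.array([8.0, 8.0, 8.0])
    nodules = [(center + np.array([0.0, 4.0, 0.0]), 8.0, None)]
    _, nods = apply_augmentation(patch, nodules, AugmentParams(scale=1.25))
    c_new, d_new, _ = nods[0]
    assert d_new == pytest.approx(10.0)
    np.testing.assert_allclose(c_new, center + np.array([0.0, 5.0, 0.0]), atol=1e-9)


def test_flip_is_exact_on_voxels_and_centers(rng):
    patch = rng.random((16, 16, 16)).astype(np.float32)
    nodules = [(np.array([4.0, 6.0, 3.0]), 5.0, None)]
    out, nods = apply_augmentation(patch, nodules, AugmentParams(flip_x=True))
    np.testing.assert_allclose(out, np.flip(patch, axis=2), atol=1e-5)
    np.testing.assert_allclose(nods[0][0], [4.0, 6.0, 12.0], atol=1e-9)


def test_rotation_keeps_intensities_in_unit_range(rng):
    patch = rng.random((16, 16, 16)).astype(np.float32)
    out, _ = apply_augmentation(patch, [], AugmentParams(angle_deg=37.0))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_transform_dropping_out_of_patch_nodule(caplog):
    import logging

    patch = np.zeros((16, 16, 16), dtype=np.float32)
    nodules = [(np.array([7.5, 7.5, 14.5]), 4.0, None)]   # near the x edge
    with caplog.at_level(logging.INFO):
        _, nods = apply_augmentation(patch, nodules, AugmentParams(scale=1.25))
    assert nods == []


def test_flip_commutes_with_anchor_assignment():
    """Flipping the patch then assigning equals assigning then flipping the
    positive anchor (exact on a stride-1 grid, where the cell-center point
    set is symmetric under the voxel-center flip)."""
    shape = (16, 16, 16)
    grid = enumerate_anchors([shape], [1])
    gt = GroundTruthBox((8.2, 5.1, 3.7), 6.0)
    flipped_center = (8.2, 5.1, (shape[2] - 1) - 3.7)
    res = assign_nearest(grid, [gt])
    res_f = assign_nearest(grid, [GroundTruthBox(flipped_center, 6.0)])
    k = int(np.nonzero(res.labels == POSITIVE)[0][0])
    kf = int(np.nonzero(res_f.labels == POSITIVE)[0][0])
    assert grid.sizes[k] == grid.sizes[kf]
    np.testing.assert_allclose(grid.points[kf],
                               [grid.points[k][0], grid.points[k][1],
                                (shape[2] - 1) - grid.points[k][2]])


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _blob_patch(size=32, center=(16, 16, 16), r=4.0, seed=0):
    rng = np.random.default_rng(seed)
    patch = (rng.random((size,) * 3) * 0.2).astype(np.float32)
    zz, yy, xx = np.ogrid[:size, :size, :size]
    c = np.asarray(center, dtype=float)
    patch[(zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r] = 0.9
    return Patch(patch, (0, 0, 0), "blob",
                 [(c, 2 * r, None)])


def tiny_model(seed=1):
    return build_model(ModelConfig(base_channels=4, neck_channels=4,
                                   cardinality=4, seed=seed))


def test_training_is_deterministic():
    patches = [_blob_patch(seed=i, center=(10 + 4 * i, 16, 16)) for i in range(2)]
    cfg = TrainConfig(epochs=2, batch_size=1, seed=3)
    h1 = train(tiny_model(), patches, cfg).history
    h2 = train(tiny_model(), patches, cfg).history
    assert h1 == h2


def test_loss_decreases_over_training():
    patches = [_blob_patch(seed=i, center=(8 + 2 * i, 16, 16)) for i in range(8)]
    cfg = TrainConfig(epochs=20, batch_size=1, seed=5)
    hist = train(tiny_model(), patches, cfg).history
    assert hist[-1]["loss"] < hist[0]["loss"]


def test_gradient_centralization_changes_updates_not_epoch0_loss():
    patches = [_blob_patch()]
    h_gc = train(tiny_model(seed=2), patches,
                 TrainConfig(epochs=3, batch_size=1, seed=4,
                             grad_centralization=True)).history
    h_no = train(tiny_model(seed=2), patches,
                 TrainConfig(epochs=3, batch_size=1, seed=4,
                             grad_centralization=False)).history
    # the first evaluated loss precedes any update -> identical
    assert h_gc[0]["loss"] == pytest.approx(h_no[0]["loss"], rel=1e-12)
    assert h_gc[-1]["loss"] != h_no[-1]["loss"]


def test_checkpoint_restores_identical_detections(tmp_path, rng):
    from noduledet.model import RPN3D

    patches = [_blob_patch()]
    model = tiny_model(seed=6)
    train(model, patches, TrainConfig(epochs=2, batch_size=1, seed=6))
    path = tmp_path / "ck.npz"
    model.save(path)
    x = rng.random((32, 32, 32)).astype(np.float32)
    a, _ = model.forward(x).flatten()
    b, _ = RPN3D.load(path).forward(x).flatten()
    np.testing.assert_array_equal(a, b)


def test_train_requires_patches():
    with pytest.raises(ValueError):
        train(tiny_model(), [], TrainConfig(epochs=1))


def test_invalid_train_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
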
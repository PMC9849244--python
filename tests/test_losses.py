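"""Boundary-weighted loss oracles and analytic anchors."""

import numpy as np
import pytest

from slhardnet.exceptions import ConfigurationError, ValidationError
from slhardnet.losses import (alt_losses, boundary_weights, structure_loss,
                              total_loss, weighted_bce, weighted_iou)
from slhardnet.network import NetworkOutputs
from slhardnet.nn.tensor import Tensor


def _random_case(rng, shape=(1, 1, 8, 8)):
    logits = Tensor(rng.normal(0.0, 3.0, size=shape).astype(np.float32))
    gt = (rng.random(shape) > 0.5).astype(np.float32)
    w = 1.0 + 5.0 * rng.random(shape).astype(np.float32)
    return logits, gt, w


# -- boundary weights ------------------------------------------------------

def test_weights_constant_masks_are_flat():
    for fill in (0.0, 1.0):
        gt = np.full((1, 1, 8, 8), fill, dtype=np.float32)
        np.testing.assert_array_equal(boundary_weights(gt), 1.0)


def test_weights_match_sliding_window_oracle():
    """Hand mean-pool (kernel 3, reflect) on an 8x8 centred 4x4 square."""
    gt = np.zeros((8, 8), dtype=np.float32)
    gt[2:6, 2:6] = 1.0
    w = boundary_weights(gt[None, None], kernel=3, omega=5.0)[0, 0]
    padded = np.pad(gt, 1, mode="reflect")
    oracle = np.empty_like(gt)
    for i in range(8):
        for j in range(8):
            oracle[i, j] = 1.0 + 5.0 * abs(
                padded[i:i + 3, j:j + 3].mean() - gt[i, j])
    np.testing.assert_allclose(w, oracle, atol=1e-6)
    assert w.min() == 1.0 and w.max() <= 6.0
    # interior and far exterior are flat, the border band is inflated
    assert w[3, 3] == 1.0 and w[0, 0] == 1.0 and w[2, 2] > 1.0


def test_weights_reject_even_kernel_and_nonbinary():
    gt = np.zeros((4, 4), dtype=np.float32)
    with pytest.raises(ConfigurationError, match="odd"):
        boundary_weights(gt, kernel=4)
    with pytest.raises(ValidationError, match="binary"):
        boundary_weights(gt + 0.5)


# -- weighted BCE ----------------------------------------------------------

def test_bce_saturated_correct_is_tiny():
    gt = np.array([[[[1.0, 0.0], [0.0, 1.0]]]], dtype=np.float32)
    logits = Tensor((2.0 * gt - 1.0) * 40.0)
    assert weighted_bce(logits, gt).item() < 1e-10


def test_bce_zero_logits_is_ln2_for_any_weights(rng):
    gt = (rng.random((1, 1, 6, 6)) > 0.3).astype(np.float32)
    w = 1.0 + 5.0 * rng.random(gt.shape).astype(np.float32)
    loss = weighted_bce(Tensor(np.zeros_like(gt)), gt, w)
    assert loss.item() == pytest.approx(np.log(2.0), abs=1e-6)


def test_bce_matches_double_loop_oracle(rng):
    logits, gt, w = _random_case(rng)
    loss = weighted_bce(logits, gt, w).item()
    num = den = 0.0
    for i in range(8):
        for j in range(8):
            z = float(logits.data[0, 0, i, j])
            g = float(gt[0, 0, i, j])
            p = 1.0 / (1.0 + np.exp(-z))
            bce = -(g * np.log(p) + (1.0 - g) * np.log(1.0 - p))
            num += w[0, 0, i, j] * bce
            den += w[0, 0, i, j]
    assert loss == pytest.approx(num / den, abs=1e-6)


# -- weighted IoU ----------------------------------------------------------

def test_iou_zero_for_perfect_binary_prediction():
    gt = np.array([[[[1.0, 1.0], [0.0, 0.0]]]], dtype=np.float32)
    logits = Tensor((2.0 * gt - 1.0) * 400.0)   # sigmoid saturates exactly
    assert weighted_iou(logits, gt).item() == pytest.approx(0.0, abs=1e-7)


def test_iou_empty_mask_stability():
    gt = np.zeros((1, 1, 4, 4), dtype=np.float32)
    logits = Tensor(np.full_like(gt, -400.0))
    assert weighted_iou(logits, gt).item() == pytest.approx(0.0, abs=1e-7)


def test_iou_matches_explicit_sum_oracle(rng):
    logits, gt, w = _random_case(rng)
    loss = weighted_iou(logits, gt, w).item()
    p = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    inter = (w * p * gt).sum()
    union = (w * (p + gt - p * gt)).sum()
    assert loss == pytest.approx(1.0 - (inter + 1.0) / (union + 1.0),
                                 abs=1e-6)


def test_iou_bounded_unit_interval(rng):
    for _ in range(10):
        logits, gt, w = _random_case(rng)
        val = weighted_iou(logits, gt, w).item()
        assert 0.0 <= val <= 1.0


# -- combined / deep supervision ------------------------------------------

def test_total_loss_symmetry_and_composition(rng):
    logits, gt, _ = _random_case(rng)
    out_same = NetworkOutputs(main_logits=logits, aux_logits=logits)
    assert total_loss(out_same, gt).item() == pytest.approx(
        2.0 * structure_loss(logits, gt).item(), rel=1e-6)

    aux = Tensor(rng.normal(size=gt.shape).astype(np.float32))
    out = NetworkOutputs(main_logits=logits, aux_logits=aux)
    w = boundary_weights(gt)
    expected = (weighted_iou(logits, gt, w).item()
                + weighted_bce(logits, gt, w).item()
                + weighted_iou(aux, gt, w).item()
                + weighted_bce(aux, gt, w).item())
    assert total_loss(out, gt).item() == pytest.approx(expected, rel=1e-6)


def test_total_loss_perfect_saturated_prediction():
    gt = np.zeros((1, 1, 8, 8), dtype=np.float32)
    gt[0, 0, 2:5, 2:5] = 1.0
    perfect = Tensor((2.0 * gt - 1.0) * 400.0)
    out = NetworkOutputs(main_logits=perfect, aux_logits=perfect)
    assert total_loss(out, gt).item() < 1e-9


def test_total_loss_monotone_towards_saturation(rng):
    gt = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
    aux = Tensor(rng.normal(size=gt.shape).astype(np.float32))
    direction = 2.0 * gt - 1.0
    values = []
    for t in np.linspace(0.5, 12.0, 8):
        out = NetworkOutputs(Tensor(direction * t), aux)
        values.append(total_loss(out, gt).item())
    assert all(a > b for a, b in zip(values, values[1:]))


def test_resolution_mismatch_rejected(rng):
    logits = Tensor(np.zeros((1, 1, 8, 8), dtype=np.float32))
    with pytest.raises(ValidationError, match="misaligned"):
        weighted_bce(logits, np.zeros((1, 1, 4, 4), dtype=np.float32))


# -- alternative losses ----------------------------------------------------

def test_dice_on_printed_2x2_toy():
    """p = [[1,1],[0,0]] (saturated), g = [[1,0],[0,0]] gives
    1 - (2*1+1)/(2+1+1) = 0.25."""
    logits = Tensor(np.array([[[[400.0, 400.0], [-400.0, -400.0]]]],
                             dtype=np.float32))
    gt = np.array([[[[1.0, 0.0], [0.0, 0.0]]]], dtype=np.float32)
    assert alt_losses(logits, gt, "dice").item() == pytest.approx(0.25,
                                                                  abs=1e-7)


def test_dice_zero_for_perfect_binary():
    gt = np.array([[[[1.0, 0.0], [1.0, 0.0]]]], dtype=np.float32)
    logits = Tensor((2.0 * gt - 1.0) * 400.0)
    assert alt_losses(logits, gt, "dice").item() == pytest.approx(0.0,
                                                                  abs=1e-7)


def test_combination_losses_compose_exactly(rng):
    logits, gt, _ = _random_case(rng)
    assert alt_losses(logits, gt, "iou+bce").item() == pytest.approx(
        alt_losses(logits, gt, "iou").item()
        + alt_losses(logits, gt, "bce").item(), rel=1e-6)
    assert alt_losses(logits, gt, "dice+bce").item() == pytest.approx(
        alt_losses(logits, gt, "dice").item()
        + alt_losses(logits, gt, "bce").item(), rel=1e-6)


def test_unknown_loss_name_lists_options(rng):
    logits, gt, _ = _random_case(rng)
    with pytest.raises(ConfigurationError, match="iou\\+bce"):
        alt_losses(logits, gt, "focal")
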
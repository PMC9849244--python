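"""Boundary-weighted segmentation losses and their unweighted relatives.

The training objective combines a weighted IoU and a weighted binary
cross-entropy, each computed from logits, with per-pixel weights inflated
near the mask boundary:

    w = 1 + ω·|meanpool_k(G) − G|        (k = 31, ω = 5 by default)

so pixels whose k×k neighbourhood disagrees with them — the ambiguous border
band — dominate the objective, while w = 1 wherever the ground truth is
locally constant.  The mean pool uses reflective padding so interior-constant
masks keep w = 1 at the image border as well.

With p = σ(logits) and weights w:

    BL = Σ w·bce(logit, g) / Σ w
    IL = 1 − (Σ w·p·g + 1) / (Σ w·(p + g − p·g) + 1)

Deep supervision sums the (IL + BL) combination over the main and the
auxiliary (CFM) branches.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ValidationError
from .nn import Tensor

__all__ = [
    "boundary_weights", "weighted_bce", "weighted_iou", "structure_loss",
    "total_loss", "alt_losses", "ALT_LOSS_NAMES",
]

ALT_LOSS_NAMES = ("iou", "bce", "dice", "dice+bce", "iou+bce")


def _check_binary(gt: np.ndarray) -> np.ndarray:
    gt = np.asarray(gt, dtype=np.float32)
    if not np.isin(gt, (0.0, 1.0)).all():
        raise ValidationError("ground-truth mask must be binary {0, 1}")
    return gt


def boundary_weights(gt: np.ndarray, kernel: int = 31,
                     omega: float = 5.0) -> np.ndarray:
    """Per-pixel weights 1 ≤ w ≤ 1 + ω, inflated near mask boundaries."""
    if kernel % 2 == 0:
        raise ConfigurationError(f"boundary kernel must be odd, got {kernel}")
    gt = _check_binary(gt)
    pooled = ndimage.uniform_filter(gt, size=_spatial_size(gt, kernel),
                                    mode="reflect")
    return 1.0 + omega * np.abs(pooled - gt)


def _spatial_size(arr: np.ndarray, kernel: int):
    """Pool over the trailing two axes only."""
    return (1,) * (arr.ndim - 2) + (kernel, kernel)


def _align(logits: Tensor, gt: np.ndarray, w: np.ndarray | None):
    gt = _check_binary(gt)
    if logits.shape != gt.shape:
        raise ValidationError(
            f"logits {logits.shape} and mask {gt.shape} are misaligned")
    if w is None:
        w = np.ones_like(gt)
    elif w.shape != gt.shape:
        raise ValidationError("weight map shape differs from the mask")
    return gt, w.astype(np.float32)


def _image_axes(shape) -> tuple:
    """Reduce over everything but the leading batch axis."""
    return tuple(range(1, len(shape)))


def weighted_bce(logits: Tensor, gt: np.ndarray,
                 w: np.ndarray | None = None) -> Tensor:
    """Weighted binary cross-entropy from logits (stable formulation).

    Reduced per image, then averaged over the batch, so small lesions are
    not drowned out by large ones.
    """
    gt, w = _align(logits, gt, w)
    axes = _image_axes(gt.shape)
    # bce(z, g) = max(z,0) - z*g + log(1 + exp(-|z|))
    per_pixel = logits.relu() - logits * gt + ((-logits.abs()).exp() + 1.0).log()
    num = (per_pixel * w).sum(axis=axes)
    return (num / w.sum(axis=axes)).mean()


def weighted_iou(logits: Tensor, gt: np.ndarray,
                 w: np.ndarray | None = None) -> Tensor:
    """Weighted soft-IoU loss in [0, 1] with +1 smoothing, per image."""
    gt, w = _align(logits, gt, w)
    axes = _image_axes(gt.shape)
    p = logits.sigmoid()
    inter = (p * gt * w).sum(axis=axes)
    union = ((p + gt - p * gt) * w).sum(axis=axes)
    return (1.0 - (inter + 1.0) / (union + 1.0)).mean()


def structure_loss(logits: Tensor, gt: np.ndarray, kernel: int = 31,
                   omega: float = 5.0) -> Tensor:
    """The IL + BL combination with boundary weights derived from ``gt``."""
    w = boundary_weights(gt, kernel, omega)
    return weighted_iou(logits, gt, w) + weighted_bce(logits, gt, w)


def total_loss(outputs, gt: np.ndarray, kernel: int = 31,
               omega: float = 5.0) -> Tensor:
    """Deep-supervision loss: structure loss of the main branch plus, when
    present, of the auxiliary branch."""
    loss = structure_loss(outputs.main_logits, gt, kernel, omega)
    if outputs.aux_logits is not None:
        loss = loss + structure_loss(outputs.aux_logits, gt, kernel, omega)
    return loss


def _dice_loss(logits: Tensor, gt: np.ndarray) -> Tensor:
    axes = _image_axes(gt.shape)
    p = logits.sigmoid()
    inter = (p * gt).sum(axis=axes)
    denom = p.sum(axis=axes) + gt.sum(axis=axes) + 1.0
    return (1.0 - (2.0 * inter + 1.0) / denom).mean()


def alt_losses(logits: Tensor, gt: np.ndarray, name: str) -> Tensor:
    """Unweighted loss alternatives for the loss-comparison harness."""
    gt, _ = _align(logits, gt, None)
    if name == "iou":
        return weighted_iou(logits, gt)
    if name == "bce":
        return weighted_bce(logits, gt)
    if name == "dice":
        return _dice_loss(logits, gt)
    if name == "dice+bce":
        return _dice_loss(logits, gt) + weighted_bce(logits, gt)
    if name == "iou+bce":
        return weighted_iou(logits, gt) + weighted_bce(logits, gt)
    raise ConfigurationError(
        f"unknown loss {name!r}; choose one of {ALT_LOSS_NAMES}")
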
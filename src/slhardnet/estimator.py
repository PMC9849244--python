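"""scikit-learn style estimator wrapping SL-HarDNet training and inference.

``LesionSegmenter`` is the package's main user-facing object: ``fit`` takes
RGB images and binary masks (lists or arrays of H×W×3 / H×W), trains the
configured network variant with the weighted IoU+BCE deep-supervision loss,
optionally tracks a validation set and keeps the best-Dice weights;
``predict`` returns binary masks at the input resolution.  It composes with
sklearn model selection through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import nn
from .data import AugmentPolicy, ImageSample, augment
from .exceptions import ConfigurationError, ValidationError
from .losses import ALT_LOSS_NAMES, alt_losses, total_loss
from .metrics import confusion, metric_report
from .network import AblationConfig, NetworkOutputs, SLHardNet
from .nn.optim import AdamW, CosineAnnealingLR

__all__ = ["LesionSegmenter", "images_to_tensor"]

# input standardisation: [0,255] -> zero mean, unit-ish scale
_MEAN, _SCALE = 0.5, 0.25


def images_to_tensor(images: np.ndarray) -> nn.Tensor:
    """N×H×W×3 uint8 → standardised N×3×H×W float tensor."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    x = (x - _MEAN) / _SCALE
    return nn.Tensor(x.transpose(0, 3, 1, 2))


def _resize_stack(images, size: int, mask: bool = False) -> np.ndarray:
    out = []
    for img in images:
        pil = Image.fromarray(np.asarray(img))
        method = Image.NEAREST if mask else Image.BILINEAR
        out.append(np.asarray(pil.resize((size, size), method)))
    return np.stack(out)


class LesionSegmenter(BaseEstimator):
    """Binary lesion segmentation with the SL-HarDNet architecture.

    Parameters follow the published recipe by default (512×512 inputs,
    batch 8, AdamW 1e-4, cosine schedule, 200 epochs, weighted IoU+BCE,
    augmentation on); desk-scale runs override ``image_size``/``epochs``.
    """

    def __init__(self, *, image_size: int = 512, batch_size: int = 8,
                 lr: float = 1e-4, epochs: int = 200,
                 weight_decay: float = 1e-2, loss: str = "iou+bce",
                 threshold: float = 0.5, use_cfm: bool = True,
                 use_scam: bool = True, use_fam: bool = True,
                 fuse_mode: str = "add", augment: bool = True,
                 boundary_kernel: int = 31, boundary_omega: float = 5.0,
                 selection_metric: str = "DIC", seed: int = 0,
                 early_stop_score: float | None = None,
                 pretrained: str | None = None, verbose: int = 0):
        self.image_size = image_size
        self.batch_size = batch_size
        self.lr = lr
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.loss = loss
        self.threshold = threshold
        self.use_cfm = use_cfm
        self.use_scam = use_scam
        self.use_fam = use_fam
        self.fuse_mode = fuse_mode
        self.augment = augment
        self.boundary_kernel = boundary_kernel
        self.boundary_omega = boundary_omega
        self.selection_metric = selection_metric
        self.seed = seed
        self.early_stop_score = early_stop_score
        self.pretrained = pretrained
        self.verbose = verbose

    # -- internals ---------------------------------------------------------
    def _check_xy(self, X, y):
        if len(X) == 0:
            raise ValidationError("empty dataset")
        if y is not None and len(X) != len(y):
            raise ValidationError("X and y lengths differ")
        if self.loss not in ALT_LOSS_NAMES:
            raise ConfigurationError(
                f"unknown loss {self.loss!r}; options: {ALT_LOSS_NAMES}")
        if self.image_size % 32:
            raise ConfigurationError("image_size must be divisible by 32")

    def _batch_loss(self, outputs: NetworkOutputs, masks: np.ndarray) -> nn.Tensor:
        gt = masks[:, None].astype(np.float32)
        if self.loss == "iou+bce":
            return total_loss(outputs, gt,
                              self.boundary_kernel, self.boundary_omega)
        loss = alt_losses(outputs.main_logits, gt, self.loss)
        if outputs.aux_logits is not None:
            loss = loss + alt_losses(outputs.aux_logits, gt, self.loss)
        return loss

    def _eval_metrics(self, images: np.ndarray, masks: np.ndarray) -> dict:
        preds = self._predict_resized(images)
        reports = [metric_report(confusion(p, g)) for p, g in zip(preds, masks)]
        return {m: float(np.mean([r[m] for r in reports]))
                for m in ("DIC", "JAC")}

    def _predict_resized(self, images: np.ndarray) -> np.ndarray:
        self.model_.eval()
        preds = []
        for lo in range(0, len(images), self.batch_size):
            x = images_to_tensor(images[lo:lo + self.batch_size])
            preds.append(self.model_.predict_mask(x, self.threshold))
        self.model_.train()
        return np.concatenate(preds)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images ``X`` and binary masks ``y``.

        An optional validation set enables per-epoch Dice tracking and
        best-weight selection; without one the final weights are kept.
        """
        self._check_xy(X, y)
        size = self.image_size
        Xr = _resize_stack(X, size)
        yr = (_resize_stack(y, size, mask=True) > 0).astype(np.uint8)
        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            Xv = _resize_stack(X_val, size)
            yv = (_resize_stack(y_val, size, mask=True) > 0).astype(np.uint8)

        nn.manual_seed(self.seed)
        self.model_ = SLHardNet(
            ablation=AblationConfig(self.use_cfm, self.use_scam, self.use_fam),
            fuse_mode=self.fuse_mode)
        if self.pretrained:
            from .checkpoint import load_encoder_weights
            load_encoder_weights(self.model_, self.pretrained)
        self.n_params_ = self.model_.num_parameters()
        opt = AdamW(self.model_.parameters(), lr=self.lr,
                    weight_decay=self.weight_decay)
        sched = CosineAnnealingLR(opt, t_max=self.epochs)
        rng = np.random.default_rng(self.seed + 1)
        policy = AugmentPolicy()

        n = len(Xr)
        history, best_state, best_score, best_epoch = [], None, -np.inf, -1
        self.model_.train()
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                imgs, msks = Xr[idx], yr[idx]
                if self.augment:
                    pairs = [augment(ImageSample(str(i), im, mk),
                                     int(rng.integers(2 ** 31 - 1)), policy)
                             for i, im, mk in zip(idx, imgs, msks)]
                    imgs = np.stack([s.image for s in pairs])
                    msks = np.stack([s.mask for s in pairs])
                x = images_to_tensor(imgs)
                out = self.model_(x)
                loss = self._batch_loss(out, msks)
                self.model_.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            row = {"epoch": epoch, "lr": opt.lr,
                   "loss": epoch_loss / max(n_batches, 1)}
            if has_val:
                scores = self._eval_metrics(Xv, yv)
                row.update({f"val_{k}": v for k, v in scores.items()})
                sel = scores.get(self.selection_metric, scores["DIC"])
                if sel > best_score:
                    best_score, best_epoch = sel, epoch
                    best_state = self.model_.state_dict()
            history.append(row)
            if self.verbose:
                print(", ".join(f"{k}={v:.4g}" if isinstance(v, float) else
                                f"{k}={v}" for k, v in row.items()))
            sched.step()
            if (has_val and self.early_stop_score is not None
                    and best_score >= self.early_stop_score):
                break
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.best_epoch_ = best_epoch if has_val else self.epochs - 1
        self.history_ = pd.DataFrame(history)
        self.model_.eval()
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "no weights loaded: call fit() or attach a checkpointed "
                "model before predicting")

    def predict_proba(self, X) -> list[np.ndarray]:
        """Lesion-probability maps at each input's native resolution."""
        self._require_fitted()
        maps = []
        for img in X:
            img = np.asarray(img)
            h, w = img.shape[:2]
            xr = _resize_stack([img], self.image_size)
            prob = self.model_.predict_proba(images_to_tensor(xr))[0, 0]
            pil = Image.fromarray(prob.astype(np.float32), mode="F")
            maps.append(np.asarray(pil.resize((w, h), Image.BILINEAR)))
        return maps

    def predict(self, X) -> list[np.ndarray]:
        """Binary masks at each input's native resolution."""
        return [(p >= self.threshold).astype(np.uint8)
                for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given set."""
        preds = self.predict(X)
        return float(np.mean([
            metric_report(confusion(p, (np.asarray(g) > 0).astype(np.uint8)))["DIC"]
            for p, g in zip(preds, y)]))
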
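"""Run orchestration: config-driven training, evaluation, ablation tables.

These functions sit between the :class:`~slhardnet.estimator.LesionSegmenter`
and the command line: they resolve datasets, create run directories with a
manifest sufficient to re-launch the run, write per-epoch logs and metric
CSVs, and drive the four-variant ablation comparison.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .checkpoint import load_checkpoint, save_checkpoint
from .config import TrainConfig
from .data import ImageSample, kfold_split
from .estimator import LesionSegmenter
from .exceptions import ValidationError
from .metrics import METRIC_NAMES, confusion, evaluate_masks, metric_report
from .network import ABLATION_VARIANTS

__all__ = ["run_training", "evaluate_checkpoint", "run_ablation",
           "write_run_manifest", "contour_overlay"]


def _estimator_from_config(cfg: TrainConfig, **overrides) -> LesionSegmenter:
    params = dict(
        image_size=cfg.resize[0], batch_size=cfg.batch_size, lr=cfg.lr,
        epochs=cfg.epochs, weight_decay=cfg.weight_decay, loss=cfg.loss,
        threshold=cfg.threshold, use_cfm=cfg.ablation.use_cfm,
        use_scam=cfg.ablation.use_scam, use_fam=cfg.ablation.use_fam,
        fuse_mode=cfg.fuse_mode, augment=cfg.augment,
        boundary_kernel=cfg.boundary_kernel, boundary_omega=cfg.boundary_omega,
        selection_metric=cfg.selection_metric, seed=cfg.seed,
        pretrained=cfg.pretrained)
    params.update(overrides)
    return LesionSegmenter(**params)


def write_run_manifest(out_dir: Path, cfg: TrainConfig, extra=None) -> None:
    import slhardnet

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "slhardnet": slhardnet.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
        "git_hash": None,   # placeholder: filled by packaging pipelines
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_training(cfg: TrainConfig, samples: list[ImageSample],
                 out_dir, fold: int = 0) -> dict:
    """Train one fold of a k-fold split of ``samples`` under ``cfg``.

    Writes ``checkpoint.npz`` (best validation weights), ``log.csv``
    (per-epoch loss/lr/val metrics) and ``manifest.json`` into ``out_dir``.
    """
    if not samples:
        raise ValidationError("empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.id: s for s in samples}
    folds = kfold_split(sorted(by_id), cfg.k_folds, cfg.seed)
    train_ids, val_ids = folds[fold]
    tr = [by_id[i] for i in train_ids]
    va = [by_id[i] for i in val_ids]

    est = _estimator_from_config(cfg)
    est.fit([s.image for s in tr], [s.mask for s in tr],
            X_val=[s.image for s in va], y_val=[s.mask for s in va])

    est.history_.to_csv(out_dir / "log.csv", index=False)
    save_checkpoint(out_dir / "checkpoint.npz", est.model_, cfg,
                    extra={"best_epoch": int(est.best_epoch_),
                           "fold": fold,
                           "val_ids": list(val_ids)})
    write_run_manifest(out_dir, cfg, extra={"fold": fold})
    return {"estimator": est, "out_dir": out_dir,
            "train_ids": train_ids, "val_ids": val_ids}


def evaluate_checkpoint(ckpt_path, samples: list[ImageSample],
                        out_csv=None) -> pd.DataFrame:
    """Per-image DIC/JAC/ACC/SEN/SPE of a checkpointed model."""
    model, cfg, _ = load_checkpoint(ckpt_path)
    est = _estimator_from_config(cfg)
    est.model_ = model
    est.n_params_ = model.num_parameters()
    preds = est.predict([s.image for s in samples])
    frame = evaluate_masks(preds, [s.mask for s in samples],
                           ids=[s.id for s in samples])
    if out_csv is not None:
        frame.to_csv(out_csv, index=False, float_format="%.6f")
    return frame


def run_ablation(cfg: TrainConfig, samples: list[ImageSample],
                 out_dir=None) -> pd.DataFrame:
    """Train the four incremental variants under one seed/data budget and
    tabulate their validation metrics and parameter counts."""
    by_id = {s.id: s for s in samples}
    folds = kfold_split(sorted(by_id), cfg.k_folds, cfg.seed)
    train_ids, val_ids = folds[0]
    tr = [by_id[i] for i in train_ids]
    va = [by_id[i] for i in val_ids]
    rows = []
    for variant in ABLATION_VARIANTS:
        est = _estimator_from_config(
            cfg, use_cfm=variant.use_cfm, use_scam=variant.use_scam,
            use_fam=variant.use_fam)
        est.fit([s.image for s in tr], [s.mask for s in tr],
                X_val=[s.image for s in va], y_val=[s.mask for s in va])
        preds = est.predict([s.image for s in va])
        reports = [metric_report(confusion(p, s.mask))
                   for p, s in zip(preds, va)]
        row = {"variant": variant.name, "params": est.n_params_}
        row.update({m: float(np.mean([r[m] for r in reports]))
                    for m in METRIC_NAMES})
        rows.append(row)
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "ablation.csv", index=False,
                     float_format="%.6f")
    return frame


def contour_overlay(image: np.ndarray, pred: np.ndarray,
                    gt: np.ndarray | None = None) -> np.ndarray:
    """Draw prediction (blue) and ground-truth (green) contours on a copy
    of the image."""
    from skimage.segmentation import find_boundaries

    out = np.asarray(image).copy()
    if gt is not None:
        out[find_boundaries(np.asarray(gt).astype(bool), mode="thick")] = \
            (0, 200, 0)
    out[find_boundaries(np.asarray(pred).astype(bool), mode="thick")] = \
        (0, 80, 255)
    return out
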
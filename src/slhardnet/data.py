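"""ISIC-style dataset I/O, the training augmentation policy, k-fold splits.

Datasets are a pair of folders — RGB images and single-channel masks with
matching file stems.  Masks are binarised at 128 on load.  Augmentation
applies vertical flip, horizontal flip, random rotation (±90°) and additive
Gaussian noise, each independently with probability 0.5; geometric
transforms act identically on image and mask (nearest-neighbour resampling
keeps the mask binary), noise touches the image only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from pathlib import Path
from scipy import ndimage
from sklearn.model_selection import KFold

from .exceptions import ValidationError

__all__ = ["ImageSample", "AugmentPolicy", "load_dataset", "augment",
           "kfold_split", "save_sample", "write_manifest"]

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class ImageSample:
    """One RGB image with its binary lesion mask."""
    id: str
    image: np.ndarray   # H×W×3 uint8
    mask: np.ndarray    # H×W uint8 in {0, 1}

    def validate(self) -> "ImageSample":
        if self.image.shape[:2] != self.mask.shape:
            raise ValidationError(
                f"{self.id}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError(f"{self.id}: mask is not binary")
        return self


@dataclass(frozen=True)
class AugmentPolicy:
    """Independent application probabilities and transform magnitudes."""
    p_vflip: float = 0.5
    p_hflip: float = 0.5
    p_rotate: float = 0.5
    p_noise: float = 0.5
    rotate_range: float = 90.0        # degrees, uniform in ±range
    noise_sigma: float = 10.0 / 255.0  # std of the additive noise, [0,1] scale


def _find_images(folder: Path) -> dict[str, Path]:
    files = {}
    for path in sorted(folder.iterdir()):
        if path.suffix.lower() in IMAGE_EXTS:
            files[path.stem] = path
    return files


def load_dataset(image_dir, mask_dir, resize: tuple[int, int] | None = None
                 ) -> list[ImageSample]:
    """Load matched image/mask pairs, sorted by stem.

    Images are resized bilinearly, masks nearest-neighbour; masks binarise
    at a grey level of 128.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    images = _find_images(image_dir)
    masks = _find_images(mask_dir)
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValidationError(
            f"unmatched stems between {image_dir} and {mask_dir}: "
            f"{orphans[:10]}")
    if not images:
        warnings.warn(f"no image/mask pairs found under {image_dir}",
                      stacklevel=2)
        return []
    samples = []
    for stem in sorted(images):
        img = Image.open(images[stem]).convert("RGB")
        msk = Image.open(masks[stem]).convert("L")
        if resize is not None:
            h, w = resize
            img = img.resize((w, h), Image.BILINEAR)
            msk = msk.resize((w, h), Image.NEAREST)
        mask = (np.asarray(msk) >= 128).astype(np.uint8)
        samples.append(ImageSample(stem, np.asarray(img, dtype=np.uint8),
                                   mask).validate())
    return samples


def _rotate_pair(image: np.ndarray, mask: np.ndarray, angle: float):
    img = ndimage.rotate(image, angle, axes=(0, 1), reshape=False,
                         order=1, mode="reflect")
    msk = ndimage.rotate(mask, angle, reshape=False, order=0, mode="reflect")
    return img, msk


def augment(sample: ImageSample, seed: int | np.random.Generator,
            policy: AugmentPolicy = AugmentPolicy()) -> ImageSample:
    """Seeded stochastic augmentation of one sample."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    do = draw_transforms(rng, policy)
    image = sample.image.astype(np.float32)
    mask = sample.mask.copy()
    if do["vflip"]:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    if do["hflip"]:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if do["rotate"]:
        angle = rng.uniform(-policy.rotate_range, policy.rotate_range)
        image, mask = _rotate_pair(image, mask, angle)
    if do["noise"]:
        image = image + rng.normal(0.0, policy.noise_sigma * 255.0,
                                   image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return replace(sample, image=image, mask=mask.astype(np.uint8)).validate()


def draw_transforms(rng: np.random.Generator,
                    policy: AugmentPolicy = AugmentPolicy()) -> dict[str, bool]:
    """Independent Bernoulli draws deciding which transforms fire."""
    return {
        "vflip": rng.random() < policy.p_vflip,
        "hflip": rng.random() < policy.p_hflip,
        "rotate": rng.random() < policy.p_rotate,
        "noise": rng.random() < policy.p_noise,
    }


def kfold_split(ids, k: int, seed: int) -> list[tuple[list, list]]:
    """Deterministic shuffled k-fold partition of ``ids`` into
    (train, validation) id lists; validation folds are disjoint, cover all
    ids and are balanced to ±1."""
    ids = list(ids)
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > len(ids):
        raise ValidationError(f"cannot split {len(ids)} ids into {k} folds")
    ids_arr = np.asarray(ids, dtype=object)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(list(ids_arr[tr]), list(ids_arr[va]))
            for tr, va in kf.split(ids_arr)]


def save_sample(sample: ImageSample, image_dir, mask_dir) -> None:
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(image_dir / f"{sample.id}.png")
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(
        mask_dir / f"{sample.id}.png")


def write_manifest(samples, folds, path) -> None:
    """CSV manifest: id, image_path, mask_path, fold index."""
    import pandas as pd

    fold_of = {}
    for i, (_, val_ids) in enumerate(folds):
        for sid in val_ids:
            fold_of[sid] = i
    rows = [{"id": s.id, "image_path": f"images/{s.id}.png",
             "mask_path": f"masks/{s.id}.png",
             "fold": fold_of.get(s.id, -1)} for s in samples]
    pd.DataFrame(rows).to_csv(path, index=False)
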
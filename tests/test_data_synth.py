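"""Dataset I/O, augmentation policy, k-fold splits and the synthetic
lesion generator."""

import numpy as np
import pytest

from slhardnet.data import (AugmentPolicy, ImageSample, augment,
                            draw_transforms, kfold_split, load_dataset,
                            save_sample)
from slhardnet.exceptions import ValidationError
from slhardnet.synth import SynthParams, make_synthetic, make_synthetic_dataset


# -- loading ---------------------------------------------------------------

def test_load_dataset_roundtrip(tmp_path, synth_96):
    for s in synth_96[:3]:
        save_sample(s, tmp_path / "images", tmp_path / "masks")
    loaded = load_dataset(tmp_path / "images", tmp_path / "masks",
                          resize=(64, 64))
    assert len(loaded) == 3
    assert [s.id for s in loaded] == sorted(s.id for s in synth_96[:3])
    for s in loaded:
        assert s.image.shape == (64, 64, 3)
        assert s.mask.shape == (64, 64)
        assert set(np.unique(s.mask)) <= {0, 1}


def test_load_dataset_reports_orphans(tmp_path, synth_96):
    save_sample(synth_96[0], tmp_path / "images", tmp_path / "masks")
    save_sample(synth_96[1], tmp_path / "images", tmp_path / "masks")
    (tmp_path / "masks" / f"{synth_96[1].id}.png").unlink()
    with pytest.raises(ValidationError, match=synth_96[1].id):
        load_dataset(tmp_path / "images", tmp_path / "masks")


def test_load_dataset_empty_folder_warns(tmp_path):
    (tmp_path / "images").mkdir()
    (tmp_path / "masks").mkdir()
    with pytest.warns(UserWarning, match="no image"):
        assert load_dataset(tmp_path / "images", tmp_path / "masks") == []


def test_mask_binarises_at_128(tmp_path):
    from PIL import Image

    (tmp_path / "images").mkdir()
    (tmp_path / "masks").mkdir()
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    msk = np.array([[0, 127, 128, 255]] * 8, dtype=np.uint8)
    msk = np.repeat(msk, 2, axis=1)
    Image.fromarray(img).save(tmp_path / "images" / "a.png")
    Image.fromarray(msk).save(tmp_path / "masks" / "a.png")
    (sample,) = load_dataset(tmp_path / "images", tmp_path / "masks")
    np.testing.assert_array_equal(np.unique(sample.mask), [0, 1])
    assert sample.mask[:, :4].sum() == 0 and sample.mask[:, 4:].all()


# -- augmentation ----------------------------------------------------------

def test_augment_deterministic(synth_96):
    a = augment(synth_96[0], seed=42)
    b = augment(synth_96[0], seed=42)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)
    c = augment(synth_96[0], seed=43)
    assert not (np.array_equal(a.image, c.image)
                and np.array_equal(a.mask, c.mask))


def test_forced_double_flip_is_identity(synth_96):
    policy = AugmentPolicy(p_vflip=1.0, p_hflip=0.0, p_rotate=0.0,
                           p_noise=0.0)
    once = augment(synth_96[0], seed=0, policy=policy)
    twice = augment(once, seed=0, policy=policy)
    np.testing.assert_array_equal(twice.image, synth_96[0].image)
    np.testing.assert_array_equal(twice.mask, synth_96[0].mask)


def test_geometric_transforms_lock_image_and_mask(synth_96):
    """An image equal to its mask stays equal under flips; under rotation
    the bilinear image and nearest mask may differ only on the boundary."""
    base = synth_96[0]
    paired = ImageSample(
        "locked", np.repeat(base.mask[:, :, None] * 255, 3, axis=2),
        base.mask)
    flips = AugmentPolicy(1.0, 1.0, 0.0, 0.0)
    out = augment(paired, seed=1, policy=flips)
    np.testing.assert_array_equal(out.image[:, :, 0], out.mask * 255)

    rot = AugmentPolicy(0.0, 0.0, 1.0, 0.0)
    out = augment(paired, seed=2, policy=rot)
    img_bin = (out.image[:, :, 0] >= 128)
    disagree = (img_bin != out.mask.astype(bool)).mean()
    assert disagree < 0.03   # only the resampled boundary band may differ


def test_noise_leaves_mask_untouched(synth_96):
    policy = AugmentPolicy(0.0, 0.0, 0.0, 1.0)
    out = augment(synth_96[0], seed=3, policy=policy)
    np.testing.assert_array_equal(out.mask, synth_96[0].mask)
    assert not np.array_equal(out.image, synth_96[0].image)


def test_transform_frequencies_match_policy():
    """Monte-Carlo check of the four independent p=0.5 Bernoulli draws."""
    rng = np.random.default_rng(99)
    counts = {"vflip": 0, "hflip": 0, "rotate": 0, "noise": 0}
    n = 10_000
    for _ in range(n):
        for k, fired in draw_transforms(rng).items():
            counts[k] += fired
    for k, c in counts.items():
        assert abs(c / n - 0.5) < 0.02, k


# -- k-fold ----------------------------------------------------------------

def test_kfold_small_exact():
    ids = [f"s{i}" for i in range(10)]
    folds = kfold_split(ids, 5, seed=0)
    val_sets = [set(v) for _, v in folds]
    assert all(len(v) == 2 for v in val_sets)
    assert set().union(*val_sets) == set(ids)
    for i, (tr, va) in enumerate(folds):
        assert set(tr) | set(va) == set(ids)
        assert not set(tr) & set(va)
    assert folds == kfold_split(ids, 5, seed=0)
    assert folds != kfold_split(ids, 5, seed=1)


def test_kfold_isic_scale_balance():
    ids = [f"ISIC_{i:07d}" for i in range(2594)]
    folds = kfold_split(ids, 5, seed=7)
    sizes = sorted(len(v) for _, v in folds)
    assert sizes == [518, 519, 519, 519, 519]
    assert set().union(*(set(v) for _, v in folds)) == set(ids)


def test_kfold_validation():
    with pytest.raises(ValidationError):
        kfold_split(["a", "b"], 3, seed=0)
    with pytest.raises(ValidationError):
        kfold_split(["a", "b"], 1, seed=0)


# -- synthetic generator ---------------------------------------------------

def test_synth_reproducible():
    p = SynthParams(canvas=(96, 96), n_blobs=2, contrast=0.3,
                    hair_strokes=3, seed=7)
    a, b = make_synthetic(p), make_synthetic(p)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)


def test_synth_lesion_interior_and_nonempty():
    s = make_synthetic(SynthParams(canvas=(96, 96), n_blobs=1, seed=7))
    assert s.mask.sum() > 0
    assert s.mask[0].sum() == 0 and s.mask[-1].sum() == 0
    assert s.mask[:, 0].sum() == 0 and s.mask[:, -1].sum() == 0


def test_synth_low_contrast_limit():
    """As contrast -> 0 the lesion is invisible up to noise."""
    p = SynthParams(canvas=(96, 96), contrast=0.01, noise_sigma=0.04,
                    seed=5, hair_strokes=0)
    s = make_synthetic(p)
    gray = s.image.mean(axis=2)
    inside = gray[s.mask == 1].mean()
    outside = gray[s.mask == 0].mean()
    assert abs(inside - outside) < 2.0 * p.noise_sigma * 255.0


def test_synth_degenerate_canvas_rejected():
    with pytest.raises(ValidationError, match="64"):
        SynthParams(canvas=(32, 96))


def test_synth_dataset_distinct_and_reproducible():
    a = make_synthetic_dataset(12, seed=0, canvas=(96, 96))
    b = make_synthetic_dataset(12, seed=0, canvas=(96, 96))
    assert len({s.id for s in a}) == 12
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.image, sb.image)
        np.testing.assert_array_equal(sa.mask, sb.mask)


def test_synth_dataset_area_spread(synth_96):
    samples = make_synthetic_dataset(80, seed=0, canvas=(96, 96))
    areas = np.array([s.mask.sum() for s in samples])
    assert areas.min() > 0
    assert areas.max() / areas.min() >= 10.0
    # binary masks throughout
    for s in samples[:10]:
        assert set(np.unique(s.mask)) <= {0, 1}
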
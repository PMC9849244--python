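"""Synthetic dermoscopy-lesion generator.

Emulates the features that make dermoscopic lesion segmentation hard:
irregular lesion outlines (Fourier-perturbed ellipses), low lesion/skin
contrast with fuzzy (Gaussian-blurred) borders, occluding hair-like strokes
drawn over both lesion and skin (never added to the mask — hair is an
occluder, not lesion), and additive pixel noise.  The ground-truth mask is
the exact rendered blob union *before* the edge blur, so boundary pixels are
genuinely ambiguous in the image but unambiguous in the label.

Every sample is a pure function of its :class:`SynthParams`, so identical
parameters give bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .data import ImageSample
from .exceptions import ValidationError

__all__ = ["SynthParams", "make_synthetic", "make_synthetic_dataset"]

#: baseline skin tone (RGB, 0-255) before per-sample jitter and gradient
_SKIN_RGB = np.array([205.0, 160.0, 140.0])


@dataclass(frozen=True)
class SynthParams:
    canvas: tuple[int, int] = (512, 512)
    n_blobs: int = 1
    contrast: float = 0.4        # lesion/skin intensity gap in (0, 1]
    hair_strokes: int = 0
    noise_sigma: float = 10.0 / 255.0
    seed: int = 0

    def __post_init__(self):
        if min(self.canvas) < 64:
            raise ValidationError(
                f"canvas {self.canvas} degenerate; need at least 64 px")
        if not 0.0 < self.contrast <= 1.0:
            raise ValidationError("contrast must lie in (0, 1]")
        if self.n_blobs < 1 or self.hair_strokes < 0 or self.noise_sigma < 0:
            raise ValidationError("invalid synthetic parameters")


def _blob_mask(rng: np.random.Generator, shape, center, r0: float
               ) -> np.ndarray:
    """Fill one Fourier-perturbed ellipse, clipped to stay interior."""
    h, w = shape
    cy, cx = center
    # radius can never reach the border: bound by distance minus a margin
    allowed = min(cy, cx, h - 1 - cy, w - 1 - cx) - 3.0
    r0 = min(r0, allowed / 1.45)
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    ecc = rng.uniform(0.7, 1.0)        # ellipse axis ratio
    phi0 = rng.uniform(0.0, np.pi)
    radius = np.full_like(theta, 1.0)
    for k in range(2, 7):              # low-order boundary wobble
        amp = rng.uniform(0.0, 0.35 / 5.0)
        radius += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
    rr = r0 * radius
    dy = rr * np.sin(theta) * ecc
    dx = rr * np.cos(theta)
    ys_r = cy + dy * np.cos(phi0) - dx * np.sin(phi0)
    xs_r = cx + dy * np.sin(phi0) + dx * np.cos(phi0)
    mask = np.zeros(shape, dtype=np.uint8)
    fy, fx = draw_polygon(np.clip(ys_r, 0, h - 1), np.clip(xs_r, 0, w - 1),
                          shape)
    mask[fy, fx] = 1
    return mask


def _bezier(rng: np.random.Generator, shape, n_pts: int = 64) -> np.ndarray:
    """Sample points along a random cubic Bézier crossing the canvas."""
    h, w = shape
    ctrl = rng.uniform([0, 0], [h - 1, w - 1], size=(4, 2))
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    b = ((1 - t) ** 3 * ctrl[0] + 3 * (1 - t) ** 2 * t * ctrl[1]
         + 3 * (1 - t) * t ** 2 * ctrl[2] + t ** 3 * ctrl[3])
    return b


def make_synthetic(params: SynthParams) -> ImageSample:
    """Render one synthetic dermoscopy sample from its parameters."""
    h, w = params.canvas
    rng = np.random.default_rng(params.seed)

    # skin background: jittered tone with a mild linear gradient
    tone = _SKIN_RGB * rng.uniform(0.9, 1.05, size=3)
    gy = rng.uniform(-0.08, 0.08)
    gx = rng.uniform(-0.08, 0.08)
    ramp = (1.0 + gy * (np.linspace(-1, 1, h)[:, None])
            + gx * (np.linspace(-1, 1, w)[None, :]))
    image = tone[None, None, :] * ramp[:, :, None]

    # lesion: union of deformed ellipses around a common centre
    scale = min(h, w)
    cy = rng.uniform(0.38, 0.62) * h
    cx = rng.uniform(0.38, 0.62) * w
    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(params.n_blobs):
        by = cy + rng.uniform(-0.05, 0.05) * h
        bx = cx + rng.uniform(-0.05, 0.05) * w
        r0 = rng.uniform(0.06, 0.24) * scale
        mask |= _blob_mask(rng, (h, w), (by, bx), r0)

    # fuzzy border: blend towards the darker lesion tone through a blurred
    # alpha; the stored mask stays the sharp pre-blur union
    lesion_tone = tone * (1.0 - params.contrast) * rng.uniform(
        0.95, 1.05, size=3)
    alpha = gaussian_filter(mask.astype(np.float32),
                            sigma=max(1.5, 0.012 * scale))
    image = image * (1.0 - alpha[:, :, None]) \
        + lesion_tone[None, None, :] * ramp[:, :, None] * alpha[:, :, None]

    # hair-like occluders, drawn over everything, absent from the mask
    for _ in range(params.hair_strokes):
        pts = _bezier(rng, (h, w))
        hair_col = rng.uniform(20.0, 70.0)
        ys = np.clip(pts[:, 0].astype(int), 0, h - 1)
        xs = np.clip(pts[:, 1].astype(int), 0, w - 1)
        for dy in (0, 1):
            yy = np.clip(ys + dy, 0, h - 1)
            image[yy, xs] = image[yy, xs] * 0.25 + hair_col * 0.75

    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma * 255.0,
                                   image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return ImageSample(f"synth_{params.seed:06d}", image, mask).validate()


def make_synthetic_dataset(n: int, seed: int = 0,
                           canvas: tuple[int, int] = (512, 512),
                           hard_fraction: float = 0.5) -> list[ImageSample]:
    """Generate ``n`` samples; about ``hard_fraction`` of them are "hard"
    (low contrast or heavy hair occlusion), the rest easy."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        hard = rng.random() < hard_fraction
        if hard:
            contrast = float(rng.uniform(0.10, 0.25))
            hair = int(rng.integers(3, 9))
        else:
            contrast = float(rng.uniform(0.30, 0.70))
            hair = int(rng.integers(0, 3))
        params = SynthParams(
            canvas=canvas,
            n_blobs=int(rng.integers(1, 4)),
            contrast=contrast,
            hair_strokes=hair,
            noise_sigma=10.0 / 255.0,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        sample = make_synthetic(params)
        samples.append(ImageSample(f"synth_{i:04d}", sample.image,
                                   sample.mask))
    return samples
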
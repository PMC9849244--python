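"""HarDNet68 encoder producing the four multi-scale taps X1..X4.

A harmonic dense block (HarDBlock) is a densely connected convolution block
in which layer ``l`` receives input only from layers ``l - 2**i`` for every
power of two dividing ``l`` (layer 0 being the block input).  Compared with a
DenseNet block this prunes most skip connections, and compensates by widening
the layers that feed many successors: layer ``l`` has
``growth * multiplier**v2(l)`` channels (``v2`` = 2-adic valuation), rounded
to the nearest even integer.  The block output concatenates the odd-indexed
layers plus the final layer and is compressed by a 1×1 transition.

The encoder stacks five 8-layer blocks behind a stride-4 stem, with spatial
halving after blocks 1, 3 and 4 so that blocks 2 and 3 share their
resolution.  Taps are taken after the transitions of blocks 1, 3, 4 and 5 at
strides 4/8/16/32 with 128/320/640/1024 channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "HarDBlockSpec", "FeaturePyramid", "HarDBlock", "HarDNetEncoder",
    "TapReducer", "harmonic_links", "layer_width",
]

#: (growth, transition out-channels) for the five blocks of HarDNet68.
HARDNET68_STAGES = ((14, 128), (16, 256), (20, 320), (40, 640), (160, 1024))
TAP_CHANNELS = (128, 320, 640, 1024)


@dataclass(frozen=True)
class HarDBlockSpec:
    """Static description of one harmonic dense block."""
    n_layers: int = 8
    growth: int = 16
    multiplier: float = 1.7
    out_channels: int = 128

    def __post_init__(self):
        if self.n_layers < 1 or self.growth < 1 or self.out_channels < 1:
            raise ConfigurationError("HarDBlockSpec fields must be positive")
        if self.multiplier <= 1.0:
            raise ConfigurationError("multiplier must exceed 1")


@dataclass
class FeaturePyramid:
    """The four encoder taps, strides 4/8/16/32, channels 128/320/640/1024."""
    x1: nn.Tensor
    x2: nn.Tensor
    x3: nn.Tensor
    x4: nn.Tensor

    def validate(self) -> "FeaturePyramid":
        taps = (self.x1, self.x2, self.x3, self.x4)
        h, w = self.x1.shape[-2], self.x1.shape[-1]
        for lvl, (t, c) in enumerate(zip(taps, TAP_CHANNELS), start=1):
            if t.shape[1] != c:
                raise ShapeError(f"tap X{lvl} has {t.shape[1]} channels, expected {c}")
            scale = 2 ** (lvl - 1)
            if t.shape[-2] * scale != h or t.shape[-1] * scale != w:
                raise ShapeError(f"tap X{lvl} spatial size off the stride ladder")
        return self


def harmonic_links(layer: int) -> list[int]:
    """Indices of the layers feeding ``layer`` (layer 0 = block input)."""
    links, i = [], 0
    while 2 ** i <= layer and layer % (2 ** i) == 0:
        links.append(layer - 2 ** i)
        i += 1
    return sorted(links)


def layer_width(layer: int, growth: int, multiplier: float) -> int:
    """Channel width of layer ``layer``: growth scaled by multiplier per
    factor of two in the index, rounded to the nearest even integer."""
    w = growth * multiplier ** _v2(layer)
    return max(2, int(round(w / 2.0) * 2))


def _v2(n: int) -> int:
    v = 0
    while n % 2 == 0 and n > 0:
        n //= 2
        v += 1
    return v


class HarDBlock(nn.Module):
    """One harmonic dense block followed by its 1×1 transition."""

    def __init__(self, in_channels: int, spec: HarDBlockSpec, index: int = 0):
        super().__init__()
        self.spec = spec
        self.index = index
        self.in_channels = in_channels
        widths = {0: in_channels}
        self.layers = []
        for l in range(1, spec.n_layers + 1):
            widths[l] = layer_width(l, spec.growth, spec.multiplier)
            cin = sum(widths[j] for j in harmonic_links(l))
            layer = nn.ConvBNReLU(cin, widths[l], kernel=3)
            self._modules[f"layer{l}"] = layer
            self.layers.append(layer)
        keep = [l for l in range(1, spec.n_layers + 1)
                if l % 2 == 1 or l == spec.n_layers]
        self.keep = keep
        concat_ch = sum(widths[l] for l in keep)
        self.transition = nn.ConvBNReLU(concat_ch, spec.out_channels, kernel=1)
        self._widths = widths

    def connectivity(self) -> dict[int, list[int]]:
        """Wiring table: layer index -> list of input layer indices."""
        return {l: harmonic_links(l) for l in range(1, self.spec.n_layers + 1)}

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"HarDBlock {self.index}: input has {x.shape[1]} channels, "
                f"configured for {self.in_channels}")
        feats = {0: x}
        for l, layer in enumerate(self.layers, start=1):
            links = harmonic_links(l)
            inp = feats[links[0]] if len(links) == 1 else nn.concat(
                [feats[j] for j in links], axis=1)
            feats[l] = layer(inp)
        out = nn.concat([feats[l] for l in self.keep], axis=1)
        return self.transition(out)


class HarDNetEncoder(nn.Module):
    """Stem + five harmonic blocks; returns the X1..X4 feature pyramid."""

    def __init__(self, stages=HARDNET68_STAGES, multiplier: float = 1.7):
        super().__init__()
        self.stem = nn.Sequential(
            nn.ConvBNReLU(3, 32, kernel=3, stride=2),
            nn.ConvBNReLU(32, 64, kernel=3),
        )
        self.stem_pool = nn.MaxPool2d(2)
        specs = [HarDBlockSpec(8, g, multiplier, c) for g, c in stages]
        in_ch = 64
        self.blocks = []
        for i, spec in enumerate(specs, start=1):
            block = HarDBlock(in_ch, spec, index=i)
            self._modules[f"block{i}"] = block
            self.blocks.append(block)
            in_ch = spec.out_channels
        self.pool = nn.MaxPool2d(2)
        self.specs = specs

    def forward(self, image: nn.Tensor) -> FeaturePyramid:
        n, c, h, w = image.shape
        if h % 32 or w % 32:
            raise ShapeError(
                f"input {h}x{w} not divisible by 32; pad or resize the image "
                "so both sides are multiples of 32")
        x = self.stem_pool(self.stem(image))          # stride 4
        x1 = self.blocks[0](x)                        # tap 1, stride 4
        x = self.pool(x1)                             # stride 8
        x = self.blocks[1](x)
        x2 = self.blocks[2](x)                        # tap 2, stride 8
        x = self.pool(x2)                             # stride 16
        x3 = self.blocks[3](x)                        # tap 3
        x = self.pool(x3)                             # stride 32
        x4 = self.blocks[4](x)                        # tap 4
        return FeaturePyramid(x1, x2, x3, x4)


class TapReducer(nn.Module):
    """Three independent 1×1 reductions of X2/X3/X4 to 32 channels;
    X1 passes through untouched."""

    def __init__(self, width: int = 32):
        super().__init__()
        self.reduce2 = nn.ConvBNReLU(TAP_CHANNELS[1], width, kernel=1)
        self.reduce3 = nn.ConvBNReLU(TAP_CHANNELS[2], width, kernel=1)
        self.reduce4 = nn.ConvBNReLU(TAP_CHANNELS[3], width, kernel=1)

    def forward(self, p: FeaturePyramid):
        return self.reduce2(p.x2), self.reduce3(p.x3), self.reduce4(p.x4)
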
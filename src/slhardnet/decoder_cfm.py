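"""Cascaded Fusion Module: progressive fusion of the reduced taps into O1.

The CFM fuses the three 32-channel taps (strides 8/16/32) in two cascaded
stages.  Each branch first passes through a Feature Pyramid Module (FPM): a
1×1 entry convolution, a four-way channel split whose chunks flow through a
*cascade* of Dilated Depthwise-style Convolution Modules (DDCM, dilations
1/3/5/7) — chunk j sees the sum of its own input and the previous chunk's
output — then a 1×1 exit convolution and a residual add of the FPM input.
With all internal weights at zero the FPM is therefore exactly the identity.

Stage 1 multiplies one FPM view of the upsampled deepest tap with the
stride-16 tap and concatenates a second FPM view; stage 2 lifts everything to
stride 8, gates the stride-8 tap with two more FPM views and concatenates an
FPM view of the stage-1 product.  Every FPM instance is independently
parameterised (five in total) and every fusion uses a 3×3 conv + BN + ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn.ops import resize_bilinear

__all__ = ["DDCMBranchSpec", "DDCM", "FPM", "CFM", "DEFAULT_DILATIONS"]

DEFAULT_DILATIONS = (1, 3, 5, 7)


@dataclass(frozen=True)
class DDCMBranchSpec:
    """One DDCM branch: odd dilation D with asymmetric-kernel pad d=(D-1)/2."""
    dilation: int

    def __post_init__(self):
        if self.dilation % 2 == 0 or self.dilation < 1:
            raise ConfigurationError(
                f"DDCM dilation must be odd and positive, got {self.dilation}")

    @property
    def asym_pad(self) -> int:
        return (self.dilation - 1) // 2


class DDCM(nn.Module):
    """1×D conv → D×1 conv → 3×3 dilated conv (dilation D), size preserving.

    The asymmetric convolutions use kernel size D with pad (D-1)/2 on the
    long axis; the dilated 3×3 uses pad D ("same" padding for kernel 3 at
    dilation D).
    """

    def __init__(self, channels: int, spec: DDCMBranchSpec):
        super().__init__()
        d_rate = spec.dilation
        d_pad = spec.asym_pad
        self.spec = spec
        self.conv_1xd = nn.ConvBNReLU(channels, channels, kernel=(1, d_rate),
                                      padding=(0, d_pad))
        self.conv_dx1 = nn.ConvBNReLU(channels, channels, kernel=(d_rate, 1),
                                      padding=(d_pad, 0))
        self.conv_dil = nn.ConvBNReLU(channels, channels, kernel=3,
                                      padding=d_rate, dilation=d_rate)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv_dil(self.conv_dx1(self.conv_1xd(x)))


class FPM(nn.Module):
    """Feature Pyramid Module with chunked DDCM cascade and residual skip."""

    def __init__(self, channels: int = 32, dilations=DEFAULT_DILATIONS):
        super().__init__()
        if channels % 4:
            raise ConfigurationError(
                f"FPM width must be divisible by 4, got {channels}")
        if len(dilations) != 4:
            raise ConfigurationError("FPM expects exactly four DDCM branches")
        self.channels = channels
        chunk = channels // 4
        self.entry = nn.ConvBNReLU(channels, channels, kernel=1)
        self.branches = []
        for i, d_rate in enumerate(dilations, start=1):
            branch = DDCM(chunk, DDCMBranchSpec(d_rate))
            self._modules[f"ddcm{i}"] = branch
            self.branches.append(branch)
        # conv-only exit: the residual add follows immediately
        self.exit = nn.Conv2d(channels, channels, kernel=1)

    def cascade(self, chunks: list[nn.Tensor]) -> list[nn.Tensor]:
        """Sequential chunk cascade: branch j sees its own chunk plus the
        previous branch's output."""
        outs = [self.branches[0](chunks[0])]
        for j in range(1, 4):
            outs.append(self.branches[j](outs[j - 1] + chunks[j]))
        return outs

    def forward(self, u: nn.Tensor) -> nn.Tensor:
        if u.shape[1] != self.channels:
            raise ConfigurationError(
                f"FPM configured for {self.channels} channels, got {u.shape[1]}")
        z = self.entry(u)
        quarter = self.channels // 4
        chunks = [z[:, i * quarter:(i + 1) * quarter] for i in range(4)]
        merged = self.exit(nn.concat(self.cascade(chunks), axis=1))
        return merged + u


class CFM(nn.Module):
    """Two-stage cascaded fusion of the reduced taps into the semantic map O1."""

    def __init__(self, width: int = 32, dilations=DEFAULT_DILATIONS):
        super().__init__()
        self.width = width
        # stage 1: two FPM views of the upsampled deepest tap
        self.fpm_a = FPM(width, dilations)
        self.fpm_b = FPM(width, dilations)
        self.fuse1 = nn.ConvBNReLU(2 * width, width, kernel=3)
        # stage 2: FPM views of the stride-8-aligned taps and the stage-1 map
        self.fpm_x3 = FPM(width, dilations)
        self.fpm_x4 = FPM(width, dilations)
        self.fpm_x43 = FPM(width, dilations)
        self.fuse2 = nn.ConvBNReLU(2 * width, width, kernel=3)

    def stage1(self, x3p: nn.Tensor, x4p: nn.Tensor) -> nn.Tensor:
        """First cascade at stride 16: X43 = F3x3(Concat(X41 ⊙ X3', X42))."""
        x4_up2 = resize_bilinear(x4p, x3p.shape[-2:])
        x41 = self.fpm_a(x4_up2)
        x42 = self.fpm_b(x4_up2)
        return self.fuse1(nn.concat([x41 * x3p, x42], axis=1))

    def stage2(self, x2p, x3p, x4p, x43) -> nn.Tensor:
        """Second cascade at stride 8 producing O1."""
        hw = x2p.shape[-2:]
        x3_up = resize_bilinear(x3p, hw)
        x4_up4 = resize_bilinear(x4p, hw)
        x43_up = resize_bilinear(x43, hw)
        gated = self.fpm_x3(x3_up) * self.fpm_x4(x4_up4) * x2p
        return self.fuse2(nn.concat([gated, self.fpm_x43(x43_up)], axis=1))

    def forward(self, x2p: nn.Tensor, x3p: nn.Tensor, x4p: nn.Tensor) -> nn.Tensor:
        h2, w2 = x2p.shape[-2:]
        h3, w3 = x3p.shape[-2:]
        if (h3 * 2, w3 * 2) != (h2, w2) or \
                (x4p.shape[-2] * 4, x4p.shape[-1] * 4) != (h2, w2):
            raise ShapeError("CFM taps are off the 8/16/32 stride ladder")
        x43 = self.stage1(x3p, x4p)
        return self.stage2(x2p, x3p, x4p, x43)
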
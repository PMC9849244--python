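"""Spatial Channel Attention Module on the low-level tap X1.

O2 = SAM(X1) + CAM(X1): a *parallel* sum of a spatially gated and a
channel-gated copy of the input (not the sequential CBAM composition).

SAM concatenates the per-pixel channel mean and channel max, passes them
through a 7×7 convolution and a sigmoid, and multiplies the resulting
(0,1) map back onto the input.  CAM pools the input globally by average and
by max, sends each descriptor through its *own* bottleneck (1×1 conv C→C/16,
ReLU, 1×1 conv C/16→C — the two stacks share no weights), sums, sigmoids and
gates the input channel-wise.
"""

from __future__ import annotations

from . import nn
from .exceptions import ConfigurationError
from .nn.ops import global_avg_pool, global_max_pool

__all__ = ["SAM", "CAM", "SCAM"]


class SAM(nn.Module):
    """Spatial attention: gate from channel-pooled statistics."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2)

    def gate(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(nn.concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.gate(x) * x


class CAM(nn.Module):
    """Channel attention with two unshared bottleneck stacks."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"CAM channels ({channels}) must be divisible by the "
                f"reduction factor ({reduction})")
        mid = channels // reduction
        self.h1 = nn.Sequential(
            nn.Conv2d(channels, mid, 1), nn.ReLU(), nn.Conv2d(mid, channels, 1))
        self.h2 = nn.Sequential(
            nn.Conv2d(channels, mid, 1), nn.ReLU(), nn.Conv2d(mid, channels, 1))

    def gate(self, x: nn.Tensor) -> nn.Tensor:
        return (self.h1(global_avg_pool(x)) + self.h2(global_max_pool(x))).sigmoid()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.gate(x) * x


class SCAM(nn.Module):
    """Parallel spatial + channel attention: O2 = SAM(x) + CAM(x)."""

    def __init__(self, channels: int = 128, reduction: int = 16,
                 sam_kernel: int = 7):
        super().__init__()
        self.sam = SAM(sam_kernel)
        self.cam = CAM(channels, reduction)

    def forward(self, x1: nn.Tensor) -> nn.Tensor:
        return self.sam(x1) + self.cam(x1)
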
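"""Feature Aggregation Module: graph-reasoned fusion of O1 and O2 into Z.

The semantic map O1 (stride 8, 32ch) is embedded twice by independent 1×1
convolutions into 16-channel maps Q and P.  The detail map O2 (stride 4,
128ch) is aligned to stride 8 once; a 1×1 conv + channel softmax turns it
into a 32-way per-pixel distribution whose *second* channel (index 1) serves
as a detail attention map.  P gated by that map is adaptively average-pooled
to a √K×√K grid of K anchor nodes V; the inner product of V with the
flattened P, softmax-normalised over pixels, gives the assignment S.  Node
features S·Q pass through one graph-reasoning unit (a learned residual
adjacency (I−A) followed by a channel-wise linear map and ReLU) and are
projected back to pixels by Sᵀ, giving Y.

In parallel the Mutual Embedding Module cross-injects a global channel
descriptor of O1 into a 32-channel view L of the detail branch and a spatial
descriptor of L into a 32-channel view Hf of O1: R = Hf'⊙L + Hf⊙L'.
The FAM output is Z = R + Conv1×1(Y).
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn.ops import adaptive_avg_pool2d, global_avg_pool, resize_bilinear

__all__ = ["GCNUnit", "MEM", "FAM"]


class GCNUnit(nn.Module):
    """One graph-reasoning block on K×Cg node features.

    out = ReLU(((I - A) · F) · W + b) with a learned K×K adjacency A
    (zero-initialised, so the unit starts as a plain channel mixer) and a
    Cg×Cg channel map W.
    """

    def __init__(self, num_nodes: int, node_dim: int):
        super().__init__()
        self.adjacency = nn.Parameter(np.zeros((num_nodes, num_nodes)))
        std = math.sqrt(2.0 / node_dim)
        rng = nn.get_rng()
        self.weight = nn.Parameter(rng.normal(0.0, std, (node_dim, node_dim)))
        self.bias = nn.Parameter(np.zeros(node_dim))

    def forward(self, fn: nn.Tensor) -> nn.Tensor:
        mixed = fn - self.adjacency @ fn
        return (mixed @ self.weight + self.bias).relu()


class MEM(nn.Module):
    """Mutual Embedding Module: R = Hf'⊙L + Hf⊙L'."""

    def __init__(self, detail_ch: int = 128, sem_ch: int = 32):
        super().__init__()
        # bias-free so a silent detail branch contributes an exactly-zero L
        self.conv_l = nn.Conv2d(detail_ch, sem_ch, 1, bias=False)
        self.conv_lp = nn.Conv2d(1, 1, 1)
        self.conv_h = nn.Conv2d(sem_ch, sem_ch, 1)
        self.conv_hp = nn.Conv2d(sem_ch, sem_ch, 1)

    def components(self, o1: nn.Tensor, o2_aligned: nn.Tensor):
        ell = self.conv_l(o2_aligned)
        ell_prime = self.conv_lp(ell.mean(axis=1, keepdims=True))
        hf = self.conv_h(o1)
        hf_prime = self.conv_hp(global_avg_pool(hf))
        return ell, ell_prime, hf, hf_prime

    def forward(self, o1: nn.Tensor, o2_aligned: nn.Tensor) -> nn.Tensor:
        ell, ell_prime, hf, hf_prime = self.components(o1, o2_aligned)
        return hf_prime * ell + hf * ell_prime


class FAM(nn.Module):
    """Graph-reasoned aggregation of semantic O1 and detail O2."""

    def __init__(self, sem_ch: int = 32, detail_ch: int = 128,
                 num_nodes: int = 16, node_dim: int = 16,
                 gcn_layers: int = 1, pool_grid: int | None = None,
                 gate_index: int = 1):
        super().__init__()
        grid = int(round(math.sqrt(num_nodes)))
        if grid * grid != num_nodes:
            raise ConfigurationError(
                f"num_nodes must be a perfect square, got {num_nodes}")
        self.grid = grid
        self.num_nodes = num_nodes
        self.node_dim = node_dim
        self.pool_grid = pool_grid or grid   # larger grid + centred crop
        if self.pool_grid < grid:
            raise ConfigurationError("pool_grid must be >= sqrt(num_nodes)")
        self.gate_index = gate_index
        self.conv_q = nn.Conv2d(sem_ch, node_dim, 1)
        self.conv_p = nn.Conv2d(sem_ch, node_dim, 1)
        self.conv_gate = nn.Conv2d(detail_ch, sem_ch, 1)
        self.gcns = []
        for i in range(gcn_layers):
            unit = GCNUnit(num_nodes, node_dim)
            self._modules[f"gcn{i}"] = unit
            self.gcns.append(unit)
        self.conv_y = nn.Conv2d(node_dim, sem_ch, 1)
        self.mem = MEM(detail_ch, sem_ch)

    # -- stages, individually exposed for inspection -----------------------
    def pixel_embed(self, o1: nn.Tensor):
        """Two independent 1×1 embeddings Q, P of the semantic map."""
        return self.conv_q(o1), self.conv_p(o1)

    def detail_gate(self, o2: nn.Tensor, out_hw=None) -> nn.Tensor:
        """1×1 conv → resize to stride 8 → channel softmax → channel 1."""
        if out_hw is None:
            out_hw = (o2.shape[-2] // 2, o2.shape[-1] // 2)
        z = self.conv_gate(o2)
        z = resize_bilinear(z, out_hw)
        probs = nn.softmax(z, axis=1)
        return probs[:, self.gate_index:self.gate_index + 1]

    def build_nodes(self, p: nn.Tensor, att: nn.Tensor) -> nn.Tensor:
        """Gate P by the detail attention and pool to K anchor nodes."""
        gated = p * att
        pooled = adaptive_avg_pool2d(gated, self.pool_grid)
        if self.pool_grid > self.grid:     # centred crop ("clipping")
            off = (self.pool_grid - self.grid) // 2
            pooled = pooled[:, :, off:off + self.grid, off:off + self.grid]
        n = p.shape[0]
        # (N, Cg, g, g) -> (N, K, Cg)
        return pooled.reshape(n, self.node_dim, self.num_nodes).transpose(0, 2, 1)

    def assign(self, v: nn.Tensor, p: nn.Tensor) -> nn.Tensor:
        """Pixel-to-node assignment S = softmax_pixels(V · Pᵀ)."""
        n, cg, h, w = p.shape
        if v.shape[-1] != cg:
            raise AssertionError("node feature dim must match P channels")
        p_flat = p.reshape(n, cg, h * w).transpose(0, 2, 1)   # (N, M, Cg)
        scores = v @ p_flat.transpose(0, 2, 1)                # (N, K, M)
        return nn.softmax(scores, axis=2)

    def graph_reason(self, s: nn.Tensor, q: nn.Tensor) -> nn.Tensor:
        """Project Q onto nodes, run the GCN unit(s), project back."""
        n, cg, h, w = q.shape
        q_flat = q.reshape(n, cg, h * w).transpose(0, 2, 1)   # (N, M, Cg)
        g = s @ q_flat                                        # (N, K, Cg)
        for unit in self.gcns:
            g = unit(g)
        y_flat = s.transpose(0, 2, 1) @ g                     # (N, M, Cg)
        return y_flat.transpose(0, 2, 1).reshape(n, cg, h, w)

    def forward(self, o1: nn.Tensor, o2: nn.Tensor) -> nn.Tensor:
        hw = (o1.shape[-2], o1.shape[-1])
        o2_aligned = resize_bilinear(o2, hw)
        q, p = self.pixel_embed(o1)
        att = self.detail_gate(o2_aligned, out_hw=hw)
        v = self.build_nodes(p, att)
        s = self.assign(v, p)
        y = self.graph_reason(s, q)
        r = self.mem(o1, o2_aligned)
        return r + self.conv_y(y)
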
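"""SL-HarDNet assembly: encoder + CFM + SCAM + FAM + supervision heads.

The full model routes the encoder pyramid through the tap reducers, builds
the semantic map O1 with the CFM, the attended detail map O2 with the SCAM,
fuses them with the FAM into Z, and produces the main logits from
Conv1×1(Conv1×1(Z) + Conv1×1(O1)) at stride 8, bilinearly upsampled ×8.
A second 1×1 head on O1 provides the deep-supervision (auxiliary) logits.

Ablation variants mirror the incremental study design:

* ``baseline``      — encoder + naive top-down decoder (upsample-add chain);
* ``+CFM``          — CFM decoder replaces the naive one, aux head appears;
* ``+CFM+SCAM``     — the SCAM branch is projected to 32 channels, aligned to
  stride 8 and summed into the decoder feature;
* ``full``          — the FAM consumes O1 and O2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention_scam import SCAM
from .backbone import HarDNetEncoder, TapReducer
from .decoder_cfm import CFM
from .exceptions import ConfigurationError
from .fusion_fam import FAM
from .nn.ops import resize_bilinear

__all__ = ["AblationConfig", "NetworkOutputs", "SLHardNet",
           "ABLATION_VARIANTS", "build_variant"]


@dataclass(frozen=True)
class AblationConfig:
    use_cfm: bool = True
    use_scam: bool = True
    use_fam: bool = True

    def __post_init__(self):
        if self.use_fam and not (self.use_cfm and self.use_scam):
            raise ConfigurationError(
                "the FAM consumes both the CFM and SCAM outputs; "
                "use_fam requires use_cfm and use_scam")

    @property
    def name(self) -> str:
        if self.use_fam:
            return "full"
        parts = [n for n, f in (("CFM", self.use_cfm), ("SCAM", self.use_scam))
                 if f]
        return "+".join(parts) if parts else "baseline"


#: The four incremental rows of the ablation study, in order.
ABLATION_VARIANTS = (
    AblationConfig(False, False, False),
    AblationConfig(True, False, False),
    AblationConfig(True, True, False),
    AblationConfig(True, True, True),
)


@dataclass
class NetworkOutputs:
    """Full-resolution logits; ``aux_logits`` is None for variants without
    the CFM deep-supervision branch."""
    main_logits: nn.Tensor
    aux_logits: nn.Tensor | None = None


class _NaiveDecoder(nn.Module):
    """Upsample-add chain over the reduced taps (baseline decoder)."""

    def __init__(self, width: int = 32):
        super().__init__()
        self.smooth = nn.ConvBNReLU(width, width, kernel=3)

    def forward(self, x2p, x3p, x4p):
        d = resize_bilinear(x4p, x3p.shape[-2:]) + x3p
        d = resize_bilinear(d, x2p.shape[-2:]) + x2p
        return self.smooth(d)


class SLHardNet(nn.Module):
    """Skin-lesion segmentation network over a HarDNet68 encoder."""

    def __init__(self, ablation: AblationConfig = AblationConfig(),
                 width: int = 32, num_nodes: int = 16, node_dim: int = 16,
                 gcn_layers: int = 1, scam_reduction: int = 16,
                 dilations=(1, 3, 5, 7), fuse_mode: str = "add"):
        super().__init__()
        if fuse_mode not in ("add", "concat"):
            raise ConfigurationError(f"unknown fuse_mode {fuse_mode!r}")
        self.ablation = ablation
        self.fuse_mode = fuse_mode
        self.encoder = HarDNetEncoder()
        self.reducer = TapReducer(width)
        if ablation.use_cfm:
            self.cfm = CFM(width, dilations)
            self.aux_head = nn.Conv2d(width, 1, 1)
        else:
            self.decoder = _NaiveDecoder(width)
        if ablation.use_scam:
            self.scam = SCAM(128, scam_reduction)
            if not ablation.use_fam:
                self.scam_proj = nn.Conv2d(128, width, 1)
        if ablation.use_fam:
            self.fam = FAM(width, 128, num_nodes, node_dim, gcn_layers)
            self.head_o = nn.Conv2d(width, width, 1)
            self.head_o1 = nn.Conv2d(width, width, 1)
            fuse_in = width if fuse_mode == "add" else 2 * width
            self.head_t = nn.Conv2d(fuse_in, 1, 1)
        else:
            self.main_head = nn.Conv2d(width, 1, 1)
        # lesions are the minority class: bias the logit heads towards
        # background at init so early training does not over-predict
        for head in ("head_t", "main_head", "aux_head"):
            if hasattr(self, head):
                getattr(self, head).bias.data[...] = -2.0

    def forward(self, image: nn.Tensor) -> NetworkOutputs:
        n, c, h, w = image.shape
        pyramid = self.encoder(image)
        x2p, x3p, x4p = self.reducer(pyramid)
        cfg = self.ablation

        aux = None
        if cfg.use_cfm:
            o1 = self.cfm(x2p, x3p, x4p)
            aux = resize_bilinear(self.aux_head(o1), (h, w))
        else:
            o1 = self.decoder(x2p, x3p, x4p)

        if cfg.use_fam:
            o2 = self.scam(pyramid.x1)
            z = self.fam(o1, o2)
            o_prime = self.head_o(z)
            o1_prime = self.head_o1(o1)
            if self.fuse_mode == "add":
                fused = o_prime + o1_prime
            else:
                fused = nn.concat([o_prime, o1_prime], axis=1)
            logits8 = self.head_t(fused)
        else:
            feat = o1
            if cfg.use_scam:
                o2 = self.scam(pyramid.x1)
                o2_al = resize_bilinear(o2, o1.shape[-2:])
                feat = feat + self.scam_proj(o2_al)
            logits8 = self.main_head(feat)

        main = resize_bilinear(logits8, (h, w))
        return NetworkOutputs(main_logits=main, aux_logits=aux)

    def predict_proba(self, image: nn.Tensor) -> np.ndarray:
        """Sigmoid of the main logits, shape N×1×H×W."""
        self.eval()
        with nn.no_grad():
            out = self.forward(image)
        return out.main_logits.sigmoid().numpy()

    def predict_mask(self, image: nn.Tensor, threshold: float = 0.5) -> np.ndarray:
        """Binary masks N×H×W at the given probability threshold."""
        if not 0.0 < threshold < 1.0:
            raise ConfigurationError("threshold must lie strictly in (0, 1)")
        probs = self.predict_proba(image)
        return (probs[:, 0] >= threshold).astype(np.uint8)


def build_variant(variant: AblationConfig, seed: int | None = None,
                  **kwargs) -> SLHardNet:
    """Construct a (seeded) network for one ablation row."""
    if seed is not None:
        nn.manual_seed(seed)
    return SLHardNet(ablation=variant, **kwargs)
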
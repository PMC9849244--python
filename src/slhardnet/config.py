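"""Serializable training configuration.

Mirrors the published training recipe: 512×512 inputs, mini-batch 8,
AdamW at 1e-4 with cosine annealing over 200 epochs, weighted IoU+BCE with
deep supervision, flip/rotation/noise augmentation at probability 0.5 each,
and best-validation-Dice model selection.  Every run serialises its config
verbatim into the checkpoint so a run can be re-launched from it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .exceptions import ConfigurationError
from .losses import ALT_LOSS_NAMES
from .metrics import METRIC_NAMES
from .network import AblationConfig

__all__ = ["TrainConfig"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr: float = 1e-4
    epochs: int = 200
    optimizer: str = "adamw"
    schedule: str = "cosine"
    weight_decay: float = 1e-2
    resize: tuple[int, int] = (512, 512)
    loss: str = "iou+bce"
    seed: int = 0
    k_folds: int = 5
    augment: bool = True
    threshold: float = 0.5
    boundary_kernel: int = 31
    boundary_omega: float = 5.0
    selection_metric: str = "DIC"
    fuse_mode: str = "add"
    pretrained: str | None = None
    ablation: AblationConfig = field(default_factory=AblationConfig)

    def __post_init__(self):
        if self.loss not in ALT_LOSS_NAMES:
            raise ConfigurationError(
                f"unknown loss {self.loss!r}; options: {ALT_LOSS_NAMES}")
        if self.selection_metric not in METRIC_NAMES:
            raise ConfigurationError(
                f"unknown selection metric {self.selection_metric!r}")
        if self.optimizer != "adamw":
            raise ConfigurationError("only the adamw optimizer is provided")
        if self.schedule != "cosine":
            raise ConfigurationError("only the cosine schedule is provided")
        if isinstance(self.ablation, dict):
            self.ablation = AblationConfig(**self.ablation)
        self.resize = tuple(self.resize)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["resize"] = list(self.resize)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
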
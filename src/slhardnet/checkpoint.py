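"""Checkpoint serialisation: weights + full config + seed in one .npz."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .config import TrainConfig
from .exceptions import ConfigurationError
from .network import SLHardNet

__all__ = ["save_checkpoint", "load_checkpoint", "load_encoder_weights"]

_META_KEY = "__meta__"


def save_checkpoint(path, model: SLHardNet, config: TrainConfig,
                    extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "extra": extra or {}}
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    arrays[_META_KEY] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[SLHardNet, TrainConfig, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint {path} does not exist")
    with np.load(path) as data:
        meta = json.loads(bytes(data[_META_KEY]).decode())
        state = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    config = TrainConfig.from_dict(meta["config"])
    nn.manual_seed(config.seed)
    model = SLHardNet(ablation=config.ablation, fuse_mode=config.fuse_mode)
    try:
        model.load_state_dict(state)
    except ValueError as exc:
        raise ConfigurationError(
            f"checkpoint weights do not match the configured network: {exc}"
        ) from exc
    model.eval()
    return model, config, meta["extra"]


def load_encoder_weights(model: SLHardNet, path) -> None:
    """Initialise the encoder from a stored checkpoint (transfer learning).

    Accepts either a full-model checkpoint written by
    :func:`save_checkpoint` or a plain ``.npz`` of encoder arrays keyed by
    the encoder's own parameter names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pretrained weights {path} do not exist")
    with np.load(path) as data:
        keys = [k for k in data.files if k != _META_KEY]
        if any(k.startswith("w::encoder.") for k in keys):
            state = {k[len("w::encoder."):]: data[k] for k in keys
                     if k.startswith("w::encoder.")}
        else:
            state = {k: data[k] for k in keys}
    try:
        model.encoder.load_state_dict(state)
    except ValueError as exc:
        raise ConfigurationError(
            f"pretrained file does not match the encoder: {exc}") from exc
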
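"""Single-file model checkpoints: config JSON + parameter tensors (npz)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..harness import TrainedModel
from .recurrent import NetConfig, build_model

__all__ = ["save_checkpoint", "load_checkpoint"]

_FORMAT_VERSION = 1


def save_checkpoint(trained: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "format_version": _FORMAT_VERSION,
        "config": trained.config.to_dict(),
        "target_offset": trained.target_offset,
        "best_epoch": trained.best_epoch,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(trained.model.parameters())}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('format_version')}")
        config = NetConfig(**header["config"])
        model = build_model(config)
        state = [data[f"param_{i}"] for i in range(len(model.parameters()))]
    model.set_state(state)
    return TrainedModel(
        model=model,
        config=config,
        target_offset=header.get("target_offset", 0.0),
        best_epoch=header.get("best_epoch", -1),
    )
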
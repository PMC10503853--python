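"""The three recurrent patch-regression architectures.

All three map normalized channel intensities to kelvin, pixel for pixel:

* **FTLSTM** — two stacked LSTM layers (hidden sizes 1024 then 612 by
  default) scan a 1×5 pixel sequence left→right; a shared fully connected
  head with dropout emits one temperature per position.
* **BFTLSTM** — two *headless* FTLSTM cores scan the sequence and its
  reversal; the reverse core's per-step features are re-reversed so both
  cores' features align by source position, are added pointwise, and pass
  through the fully connected head.
* **MFTLSTM** — a 5×5 tile is split into its five rows and five columns;
  each set feeds a headless bidirectional core. The row features and column
  features are arranged into 5×5 grids indexed by source pixel, added
  pointwise, and the head maps every pixel's fused feature to a temperature,
  giving a 5×5 output.

Directional/orientational cores have independent weights by default; a
``tie_weights`` flag makes the directions (and, for the MFTLSTM, the
row/column orientations) share parameters, which forces exact palindrome and
transpose equivariance used by the symmetry tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .nn import Dropout, Linear, LSTMLayer, Parameter

__all__ = [
    "NetConfig",
    "FTLSTM",
    "BFTLSTM",
    "MFTLSTM",
    "build_model",
    "lstm_param_count",
]

_PATCH = 5


@dataclass
class NetConfig:
    """Architecture hyperparameters shared by all three variants."""

    channels_in: int
    variant: str = "FTLSTM"
    hidden1: int = 1024
    hidden2: int = 612
    dropout: float = 0.2
    seed: int = 0
    tie_weights: bool = False
    flattened_head: bool = False
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1:
            raise ValueError("hidden sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.variant not in {"FTLSTM", "BFTLSTM", "MFTLSTM"}:
            raise ValueError(f"unknown variant {self.variant!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "channels_in": self.channels_in,
            "variant": self.variant,
            "hidden1": self.hidden1,
            "hidden2": self.hidden2,
            "dropout": self.dropout,
            "seed": self.seed,
            "tie_weights": self.tie_weights,
            "flattened_head": self.flattened_head,
            "dtype": self.dtype,
        }


def lstm_param_count(in_dim: int, hidden: int) -> int:
    """Trainable parameters of one gated recurrent layer: 4·(in+hidden+1)·hidden."""
    return 4 * (in_dim + hidden + 1) * hidden


class _Core:
    """Headless FTLSTM: two stacked LSTM layers, (B, 5, C) → (B, 5, hidden2)."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator, share_with: "_Core | None" = None):
        self.l1 = LSTMLayer(
            cfg.channels_in, cfg.hidden1, rng,
            share_with=share_with.l1 if share_with else None, dtype=cfg.dtype,
        )
        self.l2 = LSTMLayer(
            cfg.hidden1, cfg.hidden2, rng,
            share_with=share_with.l2 if share_with else None, dtype=cfg.dtype,
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.l2.forward(self.l1.forward(x, training), training)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        return self.l1.backward(self.l2.backward(dfeat))

    def parameters(self) -> list[Parameter]:
        return self.l1.parameters() + self.l2.parameters()


class _BidirCore:
    """Forward and reverse headless cores, features fused by pointwise addition.

    The reverse core scans the flipped sequence; its output is flipped back
    before the sum so that position ``k`` of the fused feature combines both
    scans' views of source pixel ``k``.
    """

    def __init__(
        self,
        cfg: NetConfig,
        rng: np.random.Generator,
        tie_directions: bool = False,
        share_with: "_BidirCore | None" = None,
    ):
        self.fwd = _Core(cfg, rng, share_with=share_with.fwd if share_with else None)
        if tie_directions:
            self.rev = _Core(cfg, rng, share_with=share_with.rev if share_with else self.fwd)
        else:
            self.rev = _Core(cfg, rng, share_with=share_with.rev if share_with else None)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.fwd.forward(x, training)
        r = self.rev.forward(x[:, ::-1], training)[:, ::-1]
        return f + r

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        dx = self.fwd.backward(dfeat)
        dx = dx + self.rev.backward(np.ascontiguousarray(dfeat[:, ::-1]))[:, ::-1]
        return dx

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.rev.parameters()


class _BaseModel:
    """Shared plumbing: parameter bookkeeping, dropout+head, state snapshots."""

    def __init__(self, config: NetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.dropout = Dropout(config.dropout, np.random.default_rng(config.seed + 1))

    def parameters(self) -> list[Parameter]:
        seen: dict[int, Parameter] = {}
        for p in self._all_parameters():
            seen.setdefault(id(p), p)
        return list(seen.values())

    def _all_parameters(self) -> list[Parameter]:  # pragma: no cover - abstract
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    def predict(self, inputs: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Deterministic evaluation-mode forward pass in minibatches."""
        outs = [
            self.forward(inputs[i : i + batch_size], training=False)
            for i in range(0, len(inputs), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError


class FTLSTM(_BaseModel):
    """One-directional sequence model: (B, 5, C) → (B, 5) kelvin."""

    def __init__(self, config: NetConfig):
        super().__init__(config)
        self.core = _Core(config, self.rng)
        self.head = Linear(config.hidden2, 1, self.rng, dtype=config.dtype)

    def _all_parameters(self) -> list[Parameter]:
        return self.core.parameters() + self.head.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        feat = self.core.forward(x, training)
        feat = self.dropout.forward(feat, training)
        return self.head.forward(feat, training)[..., 0]

    def backward(self, dout: np.ndarray) -> None:
        dfeat = self.head.backward(dout[..., None])
        dfeat = self.dropout.backward(dfeat)
        self.core.backward(dfeat)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1] != _PATCH or x.shape[2] != self.config.channels_in:
            raise ValueError(
                f"expected (N, {_PATCH}, {self.config.channels_in}) input, got {x.shape}"
            )


class BFTLSTM(_BaseModel):
    """Bidirectional sequence model: (B, 5, C) → (B, 5) kelvin."""

    def __init__(self, config: NetConfig):
        super().__init__(config)
        self.bidir = _BidirCore(config, self.rng, tie_directions=config.tie_weights)
        self.head = Linear(config.hidden2, 1, self.rng, dtype=config.dtype)

    def _all_parameters(self) -> list[Parameter]:
        return self.bidir.parameters() + self.head.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != _PATCH or x.shape[2] != self.config.channels_in:
            raise ValueError(
                f"expected (N, {_PATCH}, {self.config.channels_in}) input, got {x.shape}"
            )
        feat = self.bidir.forward(x, training)
        feat = self.dropout.forward(feat, training)
        return self.head.forward(feat, training)[..., 0]

    def backward(self, dout: np.ndarray) -> None:
        dfeat = self.head.backward(dout[..., None])
        dfeat = self.dropout.backward(dfeat)
        self.bidir.backward(dfeat)


class MFTLSTM(_BaseModel):
    """Multi-directional tile model: (B, 5, 5, C) → (B, 5, 5) kelvin.

    Row features at grid position (i, j) come from scanning row i and reading
    step j; column features at (i, j) from scanning column j and reading step
    i, so the pointwise sum fuses four directional views of source pixel
    (i, j). The head is shared across positions by default; with
    ``flattened_head`` a single 25·hidden2 → 25 affine map is used instead.
    """

    def __init__(self, config: NetConfig):
        super().__init__(config)
        self.rows = _BidirCore(config, self.rng)
        if config.tie_weights:
            self.cols = _BidirCore(config, self.rng, share_with=self.rows)
        else:
            self.cols = _BidirCore(config, self.rng)
        if config.flattened_head:
            self.head = Linear(
                _PATCH * _PATCH * config.hidden2, _PATCH * _PATCH, self.rng,
                dtype=config.dtype,
            )
        else:
            self.head = Linear(config.hidden2, 1, self.rng, dtype=config.dtype)

    def _all_parameters(self) -> list[Parameter]:
        return self.rows.parameters() + self.cols.parameters() + self.head.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if (
            x.ndim != 4
            or x.shape[1:3] != (_PATCH, _PATCH)
            or x.shape[3] != self.config.channels_in
        ):
            raise ValueError(
                f"expected (N, {_PATCH}, {_PATCH}, {self.config.channels_in}) input, "
                f"got {x.shape}"
            )
        b = x.shape[0]
        h2 = self.config.hidden2
        rows_in = x.reshape(b * _PATCH, _PATCH, -1)
        row_feat = self.rows.forward(rows_in, training).reshape(b, _PATCH, _PATCH, h2)
        cols_in = np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(b * _PATCH, _PATCH, -1)
        col_feat = (
            self.cols.forward(cols_in, training)
            .reshape(b, _PATCH, _PATCH, h2)
            .transpose(0, 2, 1, 3)
        )
        fused = row_feat + col_feat
        fused = self.dropout.forward(fused, training)
        if self.config.flattened_head:
            out = self.head.forward(fused.reshape(b, -1), training)
            return out.reshape(b, _PATCH, _PATCH)
        return self.head.forward(fused, training)[..., 0]

    def backward(self, dout: np.ndarray) -> None:
        b = dout.shape[0]
        h2 = self.config.hidden2
        if self.config.flattened_head:
            dfused = self.head.backward(dout.reshape(b, -1)).reshape(
                b, _PATCH, _PATCH, h2
            )
        else:
            dfused = self.head.backward(dout[..., None])
        dfused = self.dropout.backward(dfused)
        self.rows.backward(dfused.reshape(b * _PATCH, _PATCH, h2))
        dcol = np.ascontiguousarray(dfused.transpose(0, 2, 1, 3)).reshape(
            b * _PATCH, _PATCH, h2
        )
        self.cols.backward(dcol)


def build_model(config: NetConfig) -> _BaseModel:
    """Instantiate the architecture named by ``config.variant``."""
    cls = {"FTLSTM": FTLSTM, "BFTLSTM": BFTLSTM, "MFTLSTM": MFTLSTM}[config.variant]
    return cls(config)
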
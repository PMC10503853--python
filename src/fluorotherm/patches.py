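"""Patch extraction and stitching: the unit of work for the recurrent models.

Images are decomposed into 1×5 horizontal pixel sequences (for the sequence
models) or 5×5 tiles (for the multi-directional model), with channel counts
normalized to [0, 1]. Per-patch temperature predictions are merged back into a
full map by per-pixel averaging over every patch that covers the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fieldgen import TemperatureField
from .photophysics import GRAY_MAX, FluorescentImage

__all__ = [
    "PATCH_LEN",
    "SequenceBatch",
    "TileBatch",
    "CoverageError",
    "extract_sequences",
    "extract_tiles",
    "tile_rows_cols",
    "stitch",
]

PATCH_LEN = 5  # both the sequence length and the tile side


class CoverageError(ValueError):
    """Stitching input leaves image pixels uncovered."""


@dataclass
class SequenceBatch:
    """N horizontal runs of 5 pixels with C normalized channel intensities."""

    inputs: np.ndarray  # (N, 5, C)
    origins: np.ndarray  # (N, 2) of (row, start_col)
    targets: np.ndarray | None = None  # (N, 5) kelvin
    weights: np.ndarray | None = None  # (N, 5) per-position loss weights

    def __post_init__(self) -> None:
        if self.inputs.ndim != 3 or self.inputs.shape[1] != PATCH_LEN:
            raise ValueError(f"inputs must be (N, {PATCH_LEN}, C), got {self.inputs.shape}")

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class TileBatch:
    """N 5×5 sub-images with C normalized channel intensities."""

    inputs: np.ndarray  # (N, 5, 5, C)
    origins: np.ndarray  # (N, 2) of (top_row, left_col)
    targets: np.ndarray | None = None  # (N, 5, 5) kelvin
    weights: np.ndarray | None = None  # (N, 5, 5) per-pixel loss weights

    def __post_init__(self) -> None:
        if self.inputs.ndim != 4 or self.inputs.shape[1:3] != (PATCH_LEN, PATCH_LEN):
            raise ValueError(
                f"inputs must be (N, {PATCH_LEN}, {PATCH_LEN}, C), got {self.inputs.shape}"
            )

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _image_array(image: FluorescentImage | np.ndarray) -> np.ndarray:
    if isinstance(image, FluorescentImage):
        return image.as_array()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def extract_sequences(
    image: FluorescentImage | np.ndarray,
    field: TemperatureField | None = None,
    stride: int = 1,
    normalize: bool = True,
) -> SequenceBatch:
    """All 1×5 horizontal windows of every row, at the given column stride."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    arr = _image_array(image)
    h, w, c = arr.shape
    if w < PATCH_LEN:
        raise ValueError(f"image width {w} < sequence length {PATCH_LEN}")
    win = sliding_window_view(arr, PATCH_LEN, axis=1)[:, ::stride]  # (H, nW, C, 5)
    inputs = np.ascontiguousarray(np.moveaxis(win, -1, 2)).reshape(-1, PATCH_LEN, c)
    if normalize:
        inputs = inputs / GRAY_MAX
    n_w = win.shape[1]
    rows = np.repeat(np.arange(h), n_w)
    cols = np.tile(np.arange(0, w - PATCH_LEN + 1, stride), h)
    origins = np.stack([rows, cols], axis=1)
    targets = None
    if field is not None:
        if field.shape != (h, w):
            raise ValueError("field shape does not match image shape")
        twin = sliding_window_view(field.values, PATCH_LEN, axis=1)[:, ::stride]
        targets = np.ascontiguousarray(twin).reshape(-1, PATCH_LEN)
    return SequenceBatch(inputs=inputs, origins=origins, targets=targets)


def extract_tiles(
    image: FluorescentImage | np.ndarray,
    field: TemperatureField | None = None,
    stride: int = 1,
    normalize: bool = True,
) -> TileBatch:
    """All 5×5 windows at the given stride (both axes)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    arr = _image_array(image)
    h, w, c = arr.shape
    if h < PATCH_LEN or w < PATCH_LEN:
        raise ValueError(f"image {h}×{w} smaller than {PATCH_LEN}×{PATCH_LEN} tile")
    win = sliding_window_view(arr, (PATCH_LEN, PATCH_LEN), axis=(0, 1))
    win = win[::stride, ::stride]  # (nH, nW, C, 5, 5)
    inputs = np.ascontiguousarray(np.moveaxis(win, 2, -1)).reshape(
        -1, PATCH_LEN, PATCH_LEN, c
    )
    if normalize:
        inputs = inputs / GRAY_MAX
    n_h, n_w = win.shape[:2]
    tops = np.repeat(np.arange(0, h - PATCH_LEN + 1, stride), n_w)
    lefts = np.tile(np.arange(0, w - PATCH_LEN + 1, stride), n_h)
    origins = np.stack([tops, lefts], axis=1)
    targets = None
    if field is not None:
        if field.shape != (h, w):
            raise ValueError("field shape does not match image shape")
        twin = sliding_window_view(field.values, (PATCH_LEN, PATCH_LEN), axis=(0, 1))
        targets = np.ascontiguousarray(twin[::stride, ::stride]).reshape(
            -1, PATCH_LEN, PATCH_LEN
        )
    return TileBatch(inputs=inputs, origins=origins, targets=targets)


def tile_rows_cols(tile: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split one 5×5×C tile into its five row and five column sequences.

    Row ``i`` is ``tile[i, :, :]`` (scanned left→right) and column ``j`` is
    ``tile[:, j, :]`` (scanned top→bottom), so element ``k`` of row ``i`` and
    element ``i`` of column ``k`` both reference source pixel ``(i, k)``.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[:2] != (PATCH_LEN, PATCH_LEN):
        raise ValueError(f"tile must be ({PATCH_LEN}, {PATCH_LEN}, C), got {tile.shape}")
    rows = [tile[i, :, :] for i in range(PATCH_LEN)]
    cols = [tile[:, j, :] for j in range(PATCH_LEN)]
    return rows, cols


def stitch(
    predictions: np.ndarray,
    origins: np.ndarray,
    image_shape: tuple[int, int],
    pitch_um: float = 1.0,
) -> TemperatureField:
    """Merge overlapping per-patch predictions into one temperature map.

    Each pixel takes the mean of every patch prediction that covers it; the
    coverage-count map is kept in ``meta["coverage"]``. Accepts (N, 5)
    sequence predictions or (N, 5, 5) tile predictions.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    origins = np.asarray(origins, dtype=int)
    h, w = image_shape
    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int64)
    if predictions.ndim == 2 and predictions.shape[1] == PATCH_LEN:
        for (r, c0), pred in zip(origins, predictions):
            acc[r, c0 : c0 + PATCH_LEN] += pred
            cov[r, c0 : c0 + PATCH_LEN] += 1
    elif predictions.ndim == 3 and predictions.shape[1:] == (PATCH_LEN, PATCH_LEN):
        for (r0, c0), pred in zip(origins, predictions):
            acc[r0 : r0 + PATCH_LEN, c0 : c0 + PATCH_LEN] += pred
            cov[r0 : r0 + PATCH_LEN, c0 : c0 + PATCH_LEN] += 1
    else:
        raise ValueError(f"unsupported prediction shape {predictions.shape}")
    uncovered = np.argwhere(cov == 0)
    if uncovered.size:
        raise CoverageError(
            f"{len(uncovered)} uncovered pixels, first few: "
            f"{[tuple(px) for px in uncovered[:5]]}"
        )
    values = acc / cov
    return TemperatureField(
        values=values, pitch_um=pitch_um, meta={"generator": "stitch", "coverage": cov}
    )
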
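"""Microfluidic-chip scene emulation.

Reproduces the statistical structure of imaging a quantum-dot-filled
serpentine channel inside a heated chip: a steady-state temperature field
driven by embedded heater lines over a 290–380 K range, a binary channel mask
(fluorescence exists only where the dots are), six soft-edged filter-wheel
channels, and a single known probe point (the thermocouple) from which the
intensity–temperature calibration must be bootstrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .fieldgen import (
    FieldSpec,
    InvalidGeometryError,
    TemperatureField,
    add_temperature_noise,
    solve_steady_field,
)
from .photophysics import CalibrationModel, FluorescentImage, render_image

__all__ = [
    "ChipScene",
    "make_serpentine_mask",
    "default_chip_spec",
    "render_chip",
    "build_chip_series",
    "calibrate_from_probes",
]


@dataclass
class ChipScene:
    """One heater setting: temperature field, channel mask and probe point."""

    field: TemperatureField
    mask: np.ndarray
    probe_xy: tuple[int, int]  # (row, col)
    probe_t: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.field.shape:
            raise ValueError("mask shape must match field shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one channel pixel")
        r, c = self.probe_xy
        h, w = self.mask.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"probe {self.probe_xy} outside {h}×{w} grid")
        nr, nc = _nearest_mask_pixel(self.mask, self.probe_xy)
        self.probe_channel_xy = (nr, nc)
        self.probe_t = float(self.field.values[nr, nc])


def _nearest_mask_pixel(mask: np.ndarray, probe_xy: tuple[int, int]) -> tuple[int, int]:
    rr, cc = np.nonzero(mask)
    d2 = (rr - probe_xy[0]) ** 2 + (cc - probe_xy[1]) ** 2
    k = int(np.argmin(d2))
    return int(rr[k]), int(cc[k])


def make_serpentine_mask(
    shape: tuple[int, int],
    n_passes: int,
    channel_width_px: int,
    margin_px: int = 2,
) -> np.ndarray:
    """Binary mask of a boustrophedon channel from top to bottom.

    ``n_passes`` horizontal runs of the stated width, evenly spaced between
    ``margin_px`` and the bottom margin, joined by vertical links at
    alternating ends so the whole path is one connected component.
    """
    rows, cols = shape
    w = int(channel_width_px)
    n = int(n_passes)
    if n < 1 or w < 1:
        raise InvalidGeometryError("n_passes and channel_width_px must be >= 1")
    usable = rows - 2 * margin_px
    if usable < n * w or cols <= 2 * margin_px + w:
        raise InvalidGeometryError(
            f"serpentine with {n} passes of width {w} does not fit in {shape}"
        )
    mask = np.zeros(shape, dtype=bool)
    if n == 1:
        tops = [margin_px + (usable - w) // 2]
    else:
        gap = (usable - n * w) / (n - 1)
        tops = [margin_px + round(i * (w + gap)) for i in range(n)]
    left, right = margin_px, cols - margin_px
    for i, top in enumerate(tops):
        mask[top : top + w, left:right] = True
        if i + 1 < len(tops):
            link_cols = (
                slice(right - w, right) if i % 2 == 0 else slice(left, left + w)
            )
            mask[top : tops[i + 1] + w, link_cols] = True
    return mask


def default_chip_spec(
    shape: tuple[int, int] = (48, 48),
    ambient_k: float = 293.0,
    heater_k: float = 293.0,
    heater_cols: Sequence[int] | None = None,
    t_range: tuple[float, float] = (288.0, 382.0),
) -> FieldSpec:
    """Chip heat-solve spec: Dirichlet ambient walls + two vertical heater lines."""
    rows, cols = shape
    if heater_cols is None:
        heater_cols = (cols // 3, 2 * cols // 3)
    sources = [
        {
            "kind": "vline",
            "col": int(c),
            "row_start": rows // 6,
            "row_end": rows - rows // 6,
            "temp": float(heater_k),
        }
        for c in heater_cols
    ]
    return FieldSpec(
        kind="fd_poisson",
        shape=shape,
        params={
            "edges": {
                e: {"kind": "dirichlet", "value": float(ambient_k)}
                for e in ("top", "bottom", "left", "right")
            },
            "sources": sources,
        },
        t_range=t_range,
    )


def render_chip(
    scene: ChipScene,
    cal: CalibrationModel,
    quantize: bool = True,
    background_counts: float = 0.0,
) -> FluorescentImage:
    """Render a chip scene: full rendering, then zero counts outside the mask."""
    img = render_image(scene.field, cal, quantize=quantize)
    channels = np.where(scene.mask[None, :, :], img.channels, float(background_counts))
    meta = dict(img.meta)
    meta.update(
        probe_xy=list(scene.probe_channel_xy),
        probe_t=scene.probe_t,
        background_counts=background_counts,
        scene_meta=dict(scene.meta),
    )
    return FluorescentImage(
        channels=channels, channel_names=list(img.channel_names), meta=meta
    )


def build_chip_series(
    heater_offsets_k: Sequence[float],
    cal: CalibrationModel,
    seed: int,
    shape: tuple[int, int] = (48, 48),
    ambient_k: float = 293.0,
    n_passes: int = 4,
    channel_width_px: int = 7,
    noise_sigma_k: float = 0.1,
    probe_xy: tuple[int, int] | None = None,
) -> list[tuple[ChipScene, FluorescentImage]]:
    """One scene + image per heater setting.

    ``heater_offsets_k`` are the heater-line temperatures above ambient; the
    probe (thermocouple) temperature rises strictly with them, and a zero
    offset gives a uniform ambient field. Gaussian temperature noise is
    applied to a copy of each field before rendering; the clean field stays
    in the scene as ground truth.
    """
    if len(heater_offsets_k) < 2:
        raise ValueError("need at least 2 heater settings")
    mask = make_serpentine_mask(shape, n_passes, channel_width_px)
    if probe_xy is None:
        probe_xy = (shape[0] // 2, shape[1] // 2)
    out = []
    for i, dk in enumerate(heater_offsets_k):
        spec = default_chip_spec(shape, ambient_k=ambient_k, heater_k=ambient_k + float(dk))
        fld = solve_steady_field(spec)
        scene = ChipScene(
            field=fld,
            mask=mask,
            probe_xy=probe_xy,
            meta={"heater_offset_k": float(dk), "ambient_k": ambient_k},
        )
        render_field = fld
        if noise_sigma_k > 0:
            render_field = add_temperature_noise(fld, noise_sigma_k, seed + i)
        noisy_scene = ChipScene(
            field=render_field, mask=mask, probe_xy=probe_xy, meta=dict(scene.meta)
        )
        img = render_chip(noisy_scene, cal)
        out.append((scene, img))
    return out


def calibrate_from_probes(
    series: Sequence[tuple[ChipScene, FluorescentImage]],
    t_range: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Single-known-point calibration across a heater series.

    Only the (probe temperature, channel counts at the channel pixel nearest
    the probe) pairs are used — one per heater setting — mirroring a chip
    where the thermocouple is the sole location with known temperature. The
    resulting quadratics are then applied chip-wide.
    """
    temps = []
    counts = []
    for scene, img in series:
        r, c = scene.probe_channel_xy
        temps.append(scene.probe_t)
        counts.append(img.channels[:, r, c])
    temps_a = np.asarray(temps, dtype=np.float64)
    counts_a = np.asarray(counts, dtype=np.float64)
    if np.unique(temps_a).size < 3:
        raise ValueError("need at least 3 distinct probe temperatures")
    # counts are already on the 16-bit grayscale: fit the quadratics directly
    # (no re-anchoring), so the scale anchors are the identity map
    design = np.stack([temps_a**2, temps_a, np.ones_like(temps_a)], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, counts_a, rcond=None)
    if t_range is None:
        t_range = (float(temps_a.min()), float(temps_a.max()))
    return CalibrationModel(
        coeffs=coeffs.T,
        t_range=t_range,
        scale_anchors=(0.0, 65535.0),
        channel_names=list(series[0][1].channel_names),
    )
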
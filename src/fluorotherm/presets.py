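"""Default study conditions: QD model, filter banks, and dataset builders.

Two synthetic regimes are provided.

* The *five-band* regime: sharp-edged contiguous bands over the emission
  line, fields spanning 298–308 K, ±0.1 K pixelwise temperature noise —
  smooth analytic heat-diffusion maps rendered to 5-channel images.
* The *filter-wheel* regime: the six physical filters (550 nm long-pass,
  650 ± 20, 660 ± 5, 650 ± 5, 640 ± 5, 620 ± 5 nm FWHM) with soft, overlapping
  edges, used for chip scenes over 290–380 K; by default the 620 ± 5 channel
  is dropped for training, leaving five informative channels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fieldgen import FieldSpec, TemperatureField, add_temperature_noise, generate_field
from .photophysics import (
    CalibrationModel,
    FilterBand,
    FilterBank,
    FluorescentImage,
    QDSpectrumModel,
    calibrate_from_bank,
    render_image,
)

__all__ = [
    "default_qd_model",
    "dataset1_filterbank",
    "dataset2_filterbank",
    "dataset1_calibration",
    "dataset2_calibration",
    "random_field_spec",
    "make_dataset1",
    "DROPPED_CHANNEL",
]

#: the filter-wheel channel excluded from training (little added information)
DROPPED_CHANNEL = "620bp5"


def default_qd_model() -> QDSpectrumModel:
    """620 nm CdSe/ZnS dots: 0.1 nm/K red-shift, 0.05 nm/K broadening, 0.5 %/K quench."""
    return QDSpectrumModel()


def dataset1_filterbank() -> FilterBank:
    """Five sharp-edged contiguous bands tiling the emission line."""
    edges = [585.0, 600.0, 614.0, 628.0, 642.0, 660.0]
    bands = tuple(
        FilterBand(
            name=f"band{i}",
            kind="band-pass",
            center_nm=(lo + hi) / 2.0,
            fwhm_nm=hi - lo,
            edge_softness_nm=0.0,
        )
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    )
    return FilterBank(bands=bands)


def dataset2_filterbank(edge_softness_nm: float = 3.0) -> FilterBank:
    """The six filter-wheel bands with gradual, overlapping transitions."""
    return FilterBank(
        bands=(
            FilterBand("lp550", "long-pass", 550.0, 0.0, edge_softness_nm),
            FilterBand("650bp20", "band-pass", 650.0, 40.0, edge_softness_nm),
            FilterBand("660bp5", "band-pass", 660.0, 10.0, edge_softness_nm),
            FilterBand("650bp5", "band-pass", 650.0, 10.0, edge_softness_nm),
            FilterBand("640bp5", "band-pass", 640.0, 10.0, edge_softness_nm),
            FilterBand(DROPPED_CHANNEL, "band-pass", 620.0, 10.0, edge_softness_nm),
        )
    )


def dataset1_calibration(
    t_lo: float = 296.0, t_hi: float = 314.0, step: float = 0.5
) -> CalibrationModel:
    """Five-band calibration spanning the training range plus extrapolation headroom."""
    temps = np.arange(t_lo, t_hi + step / 2, step)
    return calibrate_from_bank(default_qd_model(), dataset1_filterbank(), temps)


def dataset2_calibration(
    t_lo: float = 288.0, t_hi: float = 382.0, step: float = 2.0
) -> CalibrationModel:
    """Six-filter calibration covering the full chip heater range."""
    temps = np.arange(t_lo, t_hi + step / 2, step)
    return calibrate_from_bank(default_qd_model(), dataset2_filterbank(), temps)


def random_field_spec(
    rng: np.random.Generator,
    shape: tuple[int, int] = (32, 32),
    t_range: tuple[float, float] = (298.0, 308.0),
    periodic_edges: bool = True,
) -> FieldSpec:
    """Draw a random analytic heat-diffusion field specification.

    Alternates between pipe cross-sections (random wall radii/temperatures and
    an off-centre axis) and plate maps (random corner temperatures); both are
    exact steady-state solutions. Optional sinusoidal edge perturbations add
    the short-wavelength boundary features that are hardest to reconstruct.
    """
    rows, cols = shape
    lo, hi = t_range
    pe = None
    if periodic_edges and rng.random() < 0.5:
        pe = {
            "amplitude_k": float(rng.uniform(0.3, 1.0)),
            "period_px": float(rng.uniform(8.0, 24.0)),
            "phase": float(rng.uniform(0, 2 * np.pi)),
        }
    if rng.random() < 0.5:
        t_i, t_o = rng.uniform(lo, hi, size=2)
        while abs(t_i - t_o) < 0.3 * (hi - lo):
            t_i, t_o = rng.uniform(lo, hi, size=2)
        r_out = rng.uniform(0.4, 0.75) * min(rows, cols)
        params = {
            "r_inner": float(rng.uniform(0.15, 0.5) * r_out),
            "r_outer": float(r_out),
            "t_inner": float(t_i),
            "t_outer": float(t_o),
            "center": (
                float(rng.uniform(0.3, 0.7) * rows),
                float(rng.uniform(0.3, 0.7) * cols),
            ),
        }
        if pe:
            params["periodic_edges"] = pe
        return FieldSpec("pipe_cross_section", shape, params, t_range)
    corners = rng.uniform(lo, hi, size=4)
    span = corners.max() - corners.min()
    if span < 0.3 * (hi - lo):  # keep some thermal contrast in every map
        corners[0] = lo + 0.1 * (hi - lo)
        corners[3] = hi - 0.1 * (hi - lo)
    params: dict = {"corners": [float(c) for c in corners]}
    if pe:
        params["periodic_edges"] = pe
    return FieldSpec("plate_dirichlet", shape, params, t_range)


def make_dataset1(
    n_images: int,
    cal: CalibrationModel,
    seed: int,
    shape: tuple[int, int] = (32, 32),
    t_range: tuple[float, float] = (298.0, 308.0),
    noise_sigma_k: float = 0.1,
    quantize: bool = True,
    specs: Sequence[FieldSpec] | None = None,
) -> list[tuple[TemperatureField, FluorescentImage]]:
    """Paired (clean ground-truth field, rendered noisy image) samples.

    The ±``noise_sigma_k`` Gaussian temperature noise is applied to a copy of
    each field *before* intensity conversion; the clean field is kept as the
    training/evaluation target, so models are scored on their ability to
    recover ground truth through the noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        spec = (
            specs[i]
            if specs is not None
            else random_field_spec(rng, shape=shape, t_range=t_range)
        )
        clean = generate_field(spec)
        render_src = clean
        if noise_sigma_k > 0:
            render_src = add_temperature_noise(
                clean, noise_sigma_k, int(rng.integers(0, 2**31 - 1))
            )
        img = render_image(render_src, cal, quantize=quantize)
        out.append((clean, img))
    return out
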
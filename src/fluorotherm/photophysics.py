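"""Temperature-dependent quantum-dot emission and the intensity pipeline.

A parametric Gaussian-line model for CdSe/ZnS quantum-dot emission (linear
peak red-shift, linear FWHM broadening, linear quenching with temperature) is
integrated over a bank of spectral filters to give per-band intensities. A
calibration run scales the band intensities to the 16-bit grayscale range
(global min → 0, global max → 65,535) and fits one 2nd-order polynomial in
temperature per channel; that quadratic map then renders temperature fields
into multi-channel 16-bit images, and can be inverted per pixel as an oracle
and as the idealized limit of the pointwise-fit baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .fieldgen import RangeError, TemperatureField

__all__ = [
    "QDSpectrumModel",
    "FilterBand",
    "FilterBank",
    "CalibrationModel",
    "FluorescentImage",
    "InversionAmbiguityError",
    "emission_spectrum",
    "band_integrate",
    "fit_calibration",
    "SpectralTable",
    "calibrate_from_table",
    "render_image",
    "pointwise_invert",
    "bin_pixels",
]

GRAY_MAX = 65535.0


class InversionAmbiguityError(ValueError):
    """No monotone channel is available for pointwise inversion."""


@dataclass(frozen=True)
class QDSpectrumModel:
    """Gaussian-line surrogate for quantum-dot emission vs temperature.

    The emission line is centred at ``peak_nm_ref + peak_shift_nm_per_k·ΔT``,
    its FWHM broadens linearly, and the integrated intensity is quenched by a
    fraction ``quench_per_k`` per kelvin above ``t_ref`` (floored at zero).
    Defaults describe 620 nm CdSe/ZnS dots.
    """

    peak_nm_ref: float = 620.0
    peak_shift_nm_per_k: float = 0.1
    fwhm_nm_ref: float = 30.0
    fwhm_broadening_nm_per_k: float = 0.05
    quench_per_k: float = 0.005
    t_ref: float = 298.0
    t_range: tuple[float, float] = (250.0, 400.0)

    def peak_nm(self, t: float) -> float:
        return self.peak_nm_ref + self.peak_shift_nm_per_k * (t - self.t_ref)

    def fwhm_nm(self, t: float) -> float:
        return self.fwhm_nm_ref + self.fwhm_broadening_nm_per_k * (t - self.t_ref)

    def total_intensity(self, t: float) -> float:
        return max(0.0, 1.0 - self.quench_per_k * (t - self.t_ref))


def emission_spectrum(
    model: QDSpectrumModel, t: float, wavelengths: np.ndarray
) -> np.ndarray:
    """Emission intensity per nm on the given wavelength grid at temperature t."""
    lo, hi = model.t_range
    if not lo <= t <= hi:
        raise RangeError(f"temperature {t} K outside model range [{lo}, {hi}] K")
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    if wavelengths.ndim != 1 or np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    fwhm = model.fwhm_nm(t)
    if fwhm <= 0:
        raise ValueError(f"non-positive FWHM ({fwhm} nm) at {t} K")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    area = model.total_intensity(t)
    peak = model.peak_nm(t)
    return (
        area
        / (sigma * np.sqrt(2.0 * np.pi))
        * np.exp(-0.5 * ((wavelengths - peak) / sigma) ** 2)
    )


@dataclass(frozen=True)
class FilterBand:
    """One spectral filter: long-pass or band-pass with logistic roll-off.

    ``edge_softness_nm`` is the logistic scale of the transition; 0 gives the
    sharp (indicator) cut used for the synthetic five-band dataset, while the
    physical filter-wheel bands use a finite softness, producing overlapping
    pass-bands.
    """

    name: str
    kind: str  # "long-pass" | "band-pass"
    center_nm: float
    fwhm_nm: float = 0.0  # unused for long-pass
    edge_softness_nm: float = 0.0

    def transmission(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=np.float64)
        s = self.edge_softness_nm
        if self.kind == "long-pass":
            if s == 0:
                return (w >= self.center_nm).astype(np.float64)
            return _logistic((w - self.center_nm) / s)
        if self.kind == "band-pass":
            lo = self.center_nm - self.fwhm_nm / 2.0
            hi = self.center_nm + self.fwhm_nm / 2.0
            if s == 0:
                return ((w >= lo) & (w <= hi)).astype(np.float64)
            return _logistic((w - lo) / s) * _logistic((hi - w) / s)
        raise ValueError(f"unknown filter kind {self.kind!r}")


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class FilterBank:
    bands: tuple[FilterBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank must contain at least one band")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


def band_integrate(
    spectrum: np.ndarray, wavelengths: np.ndarray, bank: FilterBank
) -> np.ndarray:
    """Trapezoidal integral of spectrum × transmission for every band."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    out = np.empty(len(bank))
    for i, band in enumerate(bank.bands):
        trans = band.transmission(wavelengths)
        if not np.any(trans > 0):
            warnings.warn(
                f"band {band.name!r} has no overlap with the wavelength grid",
                stacklevel=2,
            )
            out[i] = 0.0
            continue
        out[i] = np.trapezoid(spectrum * trans, wavelengths)
    return out


@dataclass
class CalibrationModel:
    """Per-channel quadratic grayscale–temperature relationship.

    ``coeffs[ch] = (a, b, c)`` predicts counts ``a·T² + b·T + c`` on the
    0–65,535 grayscale. ``scale_anchors`` records the raw band-intensity
    extremes of the calibration set that were pinned to 0 and 65,535; they are
    frozen at fit time and reused verbatim for any later data. Channels whose
    fitted quadratic is not strictly monotone over ``t_range`` carry a False
    monotone flag and are skipped by pointwise inversion.
    """

    coeffs: np.ndarray  # (C, 3) as (a, b, c)
    t_range: tuple[float, float]
    scale_anchors: tuple[float, float]  # raw (min, max) mapped to (0, GRAY_MAX)
    channel_names: list[str] = field(default_factory=list)
    monotone: np.ndarray | None = None  # (C,) bool

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64).reshape(-1, 3)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(len(self.coeffs))]
        if self.monotone is None:
            self.monotone = self._monotone_flags()
        self.monotone = np.asarray(self.monotone, dtype=bool)

    def _monotone_flags(self) -> np.ndarray:
        lo, hi = self.t_range
        a, b = self.coeffs[:, 0], self.coeffs[:, 1]
        d_lo = 2 * a * lo + b
        d_hi = 2 * a * hi + b
        return (d_lo * d_hi > 0) & (np.minimum(np.abs(d_lo), np.abs(d_hi)) > 1e-12)

    @property
    def n_channels(self) -> int:
        return len(self.coeffs)

    def predict_counts(self, t: np.ndarray) -> np.ndarray:
        """Unclipped counts, shape ``t.shape + (C,)``."""
        t = np.asarray(t, dtype=np.float64)
        a = self.coeffs[:, 0]
        b = self.coeffs[:, 1]
        c = self.coeffs[:, 2]
        return a * t[..., None] ** 2 + b * t[..., None] + c

    def scale_raw(self, raw: np.ndarray) -> np.ndarray:
        """Apply the frozen grayscale anchors to raw band intensities."""
        lo, hi = self.scale_anchors
        return (np.asarray(raw, dtype=np.float64) - lo) * (GRAY_MAX / (hi - lo))

    def select_channels(self, keep: Sequence[int] | Sequence[str]) -> "CalibrationModel":
        idx = [self.channel_names.index(k) if isinstance(k, str) else int(k) for k in keep]
        return CalibrationModel(
            coeffs=self.coeffs[idx],
            t_range=self.t_range,
            scale_anchors=self.scale_anchors,
            channel_names=[self.channel_names[i] for i in idx],
            monotone=np.asarray(self.monotone)[idx],
        )


@dataclass
class FluorescentImage:
    """Multi-channel 16-bit grayscale image, one channel per spectral band.

    ``channels`` has shape (C, H, W); counts lie in [0, 65535] and are
    integer-valued when quantized.
    """

    channels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ValueError(f"channels must be (C, H, W), got {self.channels.shape}")
        if self.channels.min() < 0 or self.channels.max() > GRAY_MAX:
            raise ValueError("counts outside the 16-bit grayscale range")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.channels.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        """Channels-last float view, shape (H, W, C)."""
        return np.moveaxis(self.channels, 0, -1)

    def select_channels(self, keep: Sequence[int] | Sequence[str]) -> "FluorescentImage":
        """Keep a subset of channels, e.g. five of the six filter-wheel bands."""
        idx = [self.channel_names.index(k) if isinstance(k, str) else int(k) for k in keep]
        return FluorescentImage(
            channels=self.channels[idx],
            channel_names=[self.channel_names[i] for i in idx],
            meta=dict(self.meta),
            bit_depth=self.bit_depth,
        )


def fit_calibration(
    temperatures: Sequence[float],
    band_intensities: np.ndarray,
    channel_names: Sequence[str] | None = None,
) -> CalibrationModel:
    """Scale raw band intensities to grayscale and fit per-channel quadratics.

    The single global minimum and maximum across the whole calibration set are
    pinned to 0 and 65,535; every intensity is mapped through that one affine
    transform, after which each channel gets an ordinary least-squares fit of
    counts as a quadratic in temperature.

    Parameters
    ----------
    temperatures
        Calibration temperatures in kelvin (≥ 3 distinct values).
    band_intensities
        Array (n_temperatures, C) of raw band integrals.
    """
    t = np.asarray(temperatures, dtype=np.float64)
    raw = np.asarray(band_intensities, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] != t.shape[0]:
        raise ValueError("band_intensities must be (n_temperatures, n_channels)")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct calibration temperatures")

    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise ValueError("calibration intensities are globally constant")
    scaled = (raw - lo) * (GRAY_MAX / (hi - lo))

    design = np.stack([t**2, t, np.ones_like(t)], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, scaled, rcond=None)
    cal = CalibrationModel(
        coeffs=coeffs.T,
        t_range=(float(t.min()), float(t.max())),
        scale_anchors=(lo, hi),
        channel_names=list(channel_names) if channel_names else [],
    )
    for ch in np.nonzero(~cal.monotone)[0]:
        warnings.warn(
            f"calibration channel {cal.channel_names[ch]!r} is not strictly "
            "monotone in temperature; flagged for inversion",
            stacklevel=2,
        )
    return cal


class SpectralTable:
    """Measured emission spectra on a (wavelength × temperature) grid.

    Loaded from CSV with header ``wavelength_nm, T1, T2, ...`` (one intensity
    column per calibration temperature in kelvin). Spectra are interpolated
    linearly in wavelength and temperature, so a measured table can stand in
    for the parametric Gaussian-line model anywhere a spectrum is needed.
    """

    def __init__(
        self,
        wavelengths: np.ndarray,
        temperatures: np.ndarray,
        intensities: np.ndarray,
    ):
        self.wavelengths = np.asarray(wavelengths, dtype=np.float64)
        self.temperatures = np.asarray(temperatures, dtype=np.float64)
        self.intensities = np.asarray(intensities, dtype=np.float64)
        if self.intensities.shape != (self.wavelengths.size, self.temperatures.size):
            raise ValueError("intensities must be (n_wavelengths, n_temperatures)")
        if np.any(np.diff(self.wavelengths) <= 0) or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("wavelengths and temperatures must be strictly increasing")
        self.t_range = (float(self.temperatures[0]), float(self.temperatures[-1]))

    @classmethod
    def from_csv(cls, path) -> "SpectralTable":
        import csv

        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0]
        temps = np.array([float(v) for v in header[1:]])
        body = np.array([[float(v) for v in row] for row in rows[1:]])
        return cls(body[:, 0], temps, body[:, 1:])

    def emission(self, t: float, wavelengths: np.ndarray) -> np.ndarray:
        lo, hi = self.t_range
        if not lo <= t <= hi:
            raise RangeError(f"temperature {t} K outside table range [{lo}, {hi}] K")
        # linear interpolation in temperature, then in wavelength
        j = int(np.searchsorted(self.temperatures, t, side="right") - 1)
        j = min(j, self.temperatures.size - 2)
        frac = (t - self.temperatures[j]) / (self.temperatures[j + 1] - self.temperatures[j])
        col = (1 - frac) * self.intensities[:, j] + frac * self.intensities[:, j + 1]
        return np.interp(wavelengths, self.wavelengths, col, left=0.0, right=0.0)


def calibrate_from_table(
    table: SpectralTable,
    bank: FilterBank,
    temperatures: "Sequence[float] | None" = None,
) -> CalibrationModel:
    """Calibration run driven by a measured spectral table instead of the model."""
    if temperatures is None:
        temperatures = table.temperatures
    raw = np.stack(
        [
            band_integrate(table.emission(t, table.wavelengths), table.wavelengths, bank)
            for t in temperatures
        ]
    )
    return fit_calibration(temperatures, raw, channel_names=bank.names)


def calibrate_from_bank(
    model: QDSpectrumModel,
    bank: FilterBank,
    temperatures: Sequence[float],
    wavelengths: np.ndarray | None = None,
) -> CalibrationModel:
    """Full calibration run: spectra → band integrals → scaling → quadratics."""
    if wavelengths is None:
        wavelengths = np.arange(450.0, 800.0, 0.25)
    raw = np.stack(
        [
            band_integrate(emission_spectrum(model, t, wavelengths), wavelengths, bank)
            for t in temperatures
        ]
    )
    return fit_calibration(temperatures, raw, channel_names=bank.names)


def render_image(
    field: TemperatureField,
    cal: CalibrationModel,
    quantize: bool = True,
    shot_noise_scale: float = 0.0,
    noise_seed: int | None = None,
) -> FluorescentImage:
    """Render a temperature field into a multi-channel grayscale image.

    Per pixel and channel, counts are the calibration quadratic evaluated at
    the pixel temperature, clipped to [0, 65,535] and (by default) rounded to
    integers with round-half-even. ``shot_noise_scale`` optionally adds
    intensity-domain noise with standard deviation scale·√counts (off by
    default: the reference pipeline puts all noise in the temperature
    domain).
    """
    lo, hi = cal.t_range
    t = field.values
    if t.min() < lo or t.max() > hi:
        bad = tuple(
            int(i) for i in np.unravel_index(int(np.argmax((t < lo) | (t > hi))), t.shape)
        )
        raise RangeError(
            f"field value {t[bad]:.3f} K at pixel {bad} outside calibration "
            f"range [{lo}, {hi}] K"
        )
    counts = cal.predict_counts(t)  # (H, W, C)
    if shot_noise_scale > 0:
        rng = np.random.default_rng(noise_seed)
        counts = counts + rng.normal(
            0.0, shot_noise_scale * np.sqrt(np.maximum(counts, 0.0))
        )
    clipped = np.count_nonzero((counts < 0) | (counts > GRAY_MAX))
    counts = np.clip(counts, 0.0, GRAY_MAX)
    if quantize:
        counts = np.round(counts)  # round-half-even
    meta = {
        "source_meta": dict(field.meta),
        "quantized": bool(quantize),
        "clipped_fraction": clipped / counts.size,
        "shot_noise_scale": shot_noise_scale,
    }
    return FluorescentImage(
        channels=np.moveaxis(counts, -1, 0),
        channel_names=list(cal.channel_names),
        meta=meta,
    )


def _invert_channel(
    counts: np.ndarray, a: float, b: float, c: float, t_range: tuple[float, float]
) -> np.ndarray:
    """Closed-form root of a·T² + b·T + (c − counts) = 0 chosen inside t_range."""
    lo, hi = t_range
    if abs(a) < 1e-300:
        return (counts - c) / b
    disc = np.maximum(b * b - 4.0 * a * (c - counts), 0.0)
    sq = np.sqrt(disc)
    r1 = (-b + sq) / (2.0 * a)
    r2 = (-b - sq) / (2.0 * a)
    # distance of each root from the validity interval; ties go to r1
    d1 = np.maximum(np.maximum(lo - r1, r1 - hi), 0.0)
    d2 = np.maximum(np.maximum(lo - r2, r2 - hi), 0.0)
    return np.where(d2 < d1, r2, r1)


def pointwise_invert(
    image: FluorescentImage,
    cal: CalibrationModel,
    channels: Sequence[int] | None = None,
) -> TemperatureField:
    """Per-pixel closed-form inversion of the calibration quadratics.

    Each monotone channel is inverted analytically (quadratic root selected
    inside the validity range); the per-channel temperature estimates are then
    combined by least squares in count space, i.e. weighted by the squared
    mean channel sensitivity |d counts/dT|. Results are clamped to the
    calibration range.
    """
    mono = np.asarray(cal.monotone)
    if channels is None:
        use = np.nonzero(mono)[0]
        if use.size == 0:
            raise InversionAmbiguityError(
                "no monotone channel available; pass channels= explicitly"
            )
    else:
        use = np.asarray(channels, dtype=int)
    lo, hi = cal.t_range
    t_mid = 0.5 * (lo + hi)
    est = np.zeros(image.shape, dtype=np.float64)
    wsum = 0.0
    for ch in use:
        a, b, c = cal.coeffs[ch]
        t_ch = _invert_channel(image.channels[ch], a, b, c, cal.t_range)
        slope = abs(2 * a * t_mid + b)  # mean sensitivity over the range
        w = slope * slope
        est += w * np.clip(t_ch, lo, hi)
        wsum += w
    if wsum == 0:
        raise InversionAmbiguityError("selected channels have zero sensitivity")
    values = est / wsum
    return TemperatureField(
        values=values,
        pitch_um=image.meta.get("source_meta", {}).get("pitch_um", 1.0),
        meta={
            "generator": "pointwise_invert",
            "channels_used": [int(ch) for ch in use],
            "t_range": [lo, hi],
        },
    )


def bin_pixels(image: FluorescentImage, factor: int) -> FluorescentImage:
    """Average ``factor × factor`` pixel blocks (camera binning).

    A trailing remainder that does not fill a block is cropped (and recorded
    in meta). Quantized inputs are re-quantized with round-half-even.
    """
    if factor <= 0:
        raise ValueError(f"binning factor must be >= 1, got {factor}")
    if factor == 1:
        return FluorescentImage(
            channels=image.channels.copy(),
            channel_names=list(image.channel_names),
            meta=dict(image.meta),
        )
    c, h, w = image.channels.shape
    hb, wb = h // factor, w // factor
    if hb == 0 or wb == 0:
        raise ValueError(f"image {h}×{w} too small for factor-{factor} binning")
    cropped = image.channels[:, : hb * factor, : wb * factor]
    blocks = cropped.reshape(c, hb, factor, wb, factor)
    out = blocks.mean(axis=(2, 4))
    if image.meta.get("quantized", True):
        out = np.round(out)
    meta = dict(image.meta)
    meta["binning"] = {"factor": int(factor), "cropped": [h - hb * factor, w - wb * factor]}
    return FluorescentImage(
        channels=out, channel_names=list(image.channel_names), meta=meta
    )
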
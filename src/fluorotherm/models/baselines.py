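"""Classical per-pixel baselines: multivariate polynomial fit and random forest.

Both regress temperature on the C channel intensities of a single pixel, with
no spatial context — exactly the standard fitting practice the recurrent
models are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

from ..fieldgen import TemperatureField
from ..patches import _image_array
from ..photophysics import GRAY_MAX, FluorescentImage

__all__ = ["MVPFPredictor", "mvpf_fit", "mvpf_predict", "rf_fit", "rf_predict"]


@dataclass
class MVPFPredictor:
    """Total-degree-2 polynomial in the channel intensities (21 terms at C=5)."""

    poly: PolynomialFeatures
    reg: LinearRegression

    @property
    def n_terms(self) -> int:
        return self.poly.n_output_features_

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.reg.predict(self.poly.transform(x))


def mvpf_fit(intensities: np.ndarray, temperatures: np.ndarray) -> MVPFPredictor:
    """Least-squares fit of T as a degree-2 polynomial (all cross terms) in C intensities."""
    x = np.asarray(intensities, dtype=np.float64)
    y = np.asarray(temperatures, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("intensities must be (N, C) matching temperatures (N,)")
    poly = PolynomialFeatures(degree=2, include_bias=True)
    design = poly.fit_transform(x)
    if x.shape[0] < poly.n_output_features_:
        raise ValueError(
            f"need at least {poly.n_output_features_} training pixels, got {x.shape[0]}"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "rank-deficient polynomial design; returning the minimum-norm solution",
            stacklevel=2,
        )
    reg = LinearRegression(fit_intercept=False)  # bias column already in the design
    reg.fit(design, y)
    return MVPFPredictor(poly=poly, reg=reg)


def _pixels(image: FluorescentImage | np.ndarray, normalize: bool) -> tuple[np.ndarray, tuple[int, int]]:
    arr = _image_array(image)
    h, w, c = arr.shape
    x = arr.reshape(-1, c)
    if normalize:
        x = x / GRAY_MAX
    return x, (h, w)


def mvpf_predict(
    predictor: MVPFPredictor,
    image: FluorescentImage | np.ndarray,
    normalize: bool = True,
    pitch_um: float = 1.0,
) -> TemperatureField:
    """Apply the polynomial pixel by pixel to a whole image."""
    x, shape = _pixels(image, normalize)
    values = predictor.predict(x).reshape(shape)
    return TemperatureField(values=values, pitch_um=pitch_um, meta={"generator": "mvpf"})


def rf_fit(
    intensities: np.ndarray,
    temperatures: np.ndarray,
    n_estimators: int = 200,
    max_depth: int | None = None,
    max_features: str | int | float = "sqrt",
    seed: int = 0,
) -> RandomForestRegressor:
    """Regression forest on per-pixel intensities (200 trees, √C features by default)."""
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(intensities, dtype=np.float64), np.asarray(temperatures).ravel())
    return rf


def rf_predict(
    predictor: RandomForestRegressor,
    image: FluorescentImage | np.ndarray,
    normalize: bool = True,
    pitch_um: float = 1.0,
) -> TemperatureField:
    """Apply the forest pixel by pixel to a whole image."""
    x, shape = _pixels(image, normalize)
    values = predictor.predict(x).reshape(shape)
    return TemperatureField(values=values, pitch_um=pitch_um, meta={"generator": "rf"})
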
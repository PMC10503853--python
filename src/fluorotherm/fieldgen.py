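"""Ground-truth temperature fields from the steady-state heat equation.

Two closed-form families (annular pipe cross-section, rectangular plate with
harmonic corner blending) and a finite-difference Laplace solver with Dirichlet
edges, mirror (insulated) edges and interior fixed-temperature heater lines.
Pixelwise Gaussian temperature noise is applied *before* any intensity
conversion, matching the simulation pipeline the networks are trained on.

Coordinate convention: row-major, 0-based, ``(row, col) = (y, x)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TemperatureField",
    "FieldSpec",
    "InvalidGeometryError",
    "RangeError",
    "ConvergenceError",
    "generate_pipe_field",
    "generate_plate_field",
    "solve_steady_field",
    "generate_field",
    "add_temperature_noise",
]


class InvalidGeometryError(ValueError):
    """Raised when a field specification's geometry is inconsistent."""


class RangeError(ValueError):
    """Raised when temperatures fall outside the declared validity window."""


class ConvergenceError(RuntimeError):
    """Raised when the steady-state solve fails the residual contract."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        self.tol = tol
        super().__init__(f"max interior residual {residual:.3e} K exceeds tol {tol:.3e} K")


@dataclass
class TemperatureField:
    """A 2-D grid of temperatures in kelvin with a physical pixel pitch.

    Parameters
    ----------
    values
        2-D float array of temperatures (K).
    pitch_um
        Pixel pitch in micrometres; gradients derived from this field are in
        K/μm. Default 1 μm.
    meta
        Free-form provenance record (generator name, parameters, seed,
        ``t_range``).
    """

    values: np.ndarray
    pitch_um: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **meta_updates: Any) -> "TemperatureField":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return TemperatureField(values=values, pitch_um=self.pitch_um, meta=meta)


@dataclass
class FieldSpec:
    """Parameters of one ground-truth field family.

    ``kind`` selects the family: ``pipe_cross_section`` (annulus closed form),
    ``plate_dirichlet`` (harmonic bilinear corner blend) or ``fd_poisson``
    (finite-difference Laplace solve). Geometry lives in ``params`` in pixel
    coordinates; all temperatures are kelvin and must lie inside ``t_range``.
    """

    kind: str
    shape: tuple[int, int]
    params: dict[str, Any] = field(default_factory=dict)
    t_range: tuple[float, float] = (298.0, 308.0)

    def __post_init__(self) -> None:
        if self.kind not in {"pipe_cross_section", "plate_dirichlet", "fd_poisson"}:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise InvalidGeometryError(f"bad shape {self.shape}")
        if not self.t_range[0] < self.t_range[1]:
            raise RangeError(f"t_min must be < t_max, got {self.t_range}")


def _check_range(values: np.ndarray, t_range: tuple[float, float], what: str) -> None:
    lo, hi = t_range
    if values.min() < lo - 1e-9 or values.max() > hi + 1e-9:
        raise RangeError(
            f"{what} spans [{values.min():.3f}, {values.max():.3f}] K, "
            f"outside declared t_range [{lo}, {hi}] K"
        )


def _periodic_edge_perturbation(
    shape: tuple[int, int], amplitude_k: float, period_px: float, phase: float = 0.0
) -> np.ndarray:
    """Harmonic perturbation driven by sinusoidal top/bottom boundary data.

    ``A sin(2πx/λ + φ) exp(−2πd/λ)`` for each horizontal edge, with ``d`` the
    distance from that edge, is an exact solution of the Laplace equation, so
    adding it keeps the field a steady-state heat solution while creating the
    short-wavelength edge features that are hardest to reconstruct.
    """
    rows, cols = shape
    x = np.arange(cols, dtype=np.float64)
    wave = amplitude_k * np.sin(2 * np.pi * x / period_px + phase)
    k = 2 * np.pi / period_px
    d_top = np.arange(rows, dtype=np.float64)[:, None]
    d_bot = d_top[::-1]
    return wave[None, :] * (np.exp(-k * d_top) + np.exp(-k * d_bot))


def generate_pipe_field(
    spec: FieldSpec, noise_seed: int | None = None
) -> TemperatureField:
    """Closed-form conduction through a pipe wall, viewed in cross-section.

    Inside radius ``r_inner`` the field is the inner wall temperature
    ``t_inner``; outside ``r_outer`` it is ``t_outer``; in the annulus it is
    the logarithmic steady-state profile

        T(r) = t_inner + (t_outer − t_inner) · ln(r / r_inner) / ln(r_outer / r_inner).

    ``params`` keys: ``r_inner``, ``r_outer`` (px), ``t_inner``, ``t_outer``
    (K), optional ``center`` ((row, col), default grid centre), optional
    ``periodic_edges`` (dict with ``amplitude_k``/``period_px``/``phase``,
    default off) and ``noise_sigma_k`` (used only when ``noise_seed`` given,
    default 0.1 K).
    """
    if spec.kind != "pipe_cross_section":
        raise ValueError("spec.kind must be 'pipe_cross_section'")
    p = spec.params
    r_i, r_o = float(p["r_inner"]), float(p["r_outer"])
    t_i, t_o = float(p["t_inner"]), float(p["t_outer"])
    if r_i >= r_o:
        raise InvalidGeometryError(f"r_inner ({r_i}) must be < r_outer ({r_o})")
    if r_i <= 0:
        raise InvalidGeometryError("r_inner must be > 0")
    for t in (t_i, t_o):
        if not spec.t_range[0] <= t <= spec.t_range[1]:
            raise RangeError(f"wall temperature {t} K outside t_range {spec.t_range}")

    rows, cols = spec.shape
    center = p.get("center", ((rows - 1) / 2.0, (cols - 1) / 2.0))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r = np.hypot(rr - center[0], cc - center[1])

    values = np.full(spec.shape, t_i, dtype=np.float64)
    ann = (r >= r_i) & (r <= r_o)
    with np.errstate(divide="ignore"):
        values[ann] = t_i + (t_o - t_i) * np.log(r[ann] / r_i) / np.log(r_o / r_i)
    values[r > r_o] = t_o

    pe = p.get("periodic_edges")
    if pe:
        values = values + _periodic_edge_perturbation(
            spec.shape,
            amplitude_k=pe.get("amplitude_k", 1.0),
            period_px=pe.get("period_px", 16.0),
            phase=pe.get("phase", 0.0),
        )
        values = np.clip(values, spec.t_range[0], spec.t_range[1])

    _check_range(values, spec.t_range, "pipe field")
    fld = TemperatureField(
        values=values,
        pitch_um=p.get("pitch_um", 1.0),
        meta={
            "generator": "generate_pipe_field",
            "spec": {"kind": spec.kind, "shape": list(spec.shape), **_jsonable(p)},
            "t_range": list(spec.t_range),
        },
    )
    if noise_seed is not None:
        fld = add_temperature_noise(fld, p.get("noise_sigma_k", 0.1), noise_seed)
    return fld


def generate_plate_field(
    spec: FieldSpec, noise_seed: int | None = None
) -> TemperatureField:
    """Rectangular plate with the four corner temperatures blended bilinearly.

    The bilinear blend a + b·x + c·y + d·x·y is harmonic, so this is an exact
    steady-state solution with Dirichlet edges that interpolate the corners.
    ``params``: ``corners`` = (T_tl, T_tr, T_bl, T_br) in kelvin, optional
    ``periodic_edges`` as in :func:`generate_pipe_field`.
    """
    if spec.kind != "plate_dirichlet":
        raise ValueError("spec.kind must be 'plate_dirichlet'")
    p = spec.params
    t_tl, t_tr, t_bl, t_br = (float(t) for t in p["corners"])
    for t in (t_tl, t_tr, t_bl, t_br):
        if not spec.t_range[0] <= t <= spec.t_range[1]:
            raise RangeError(f"corner temperature {t} K outside t_range {spec.t_range}")
    rows, cols = spec.shape
    y = np.linspace(0.0, 1.0, rows)[:, None]
    x = np.linspace(0.0, 1.0, cols)[None, :]
    values = (
        t_tl * (1 - x) * (1 - y)
        + t_tr * x * (1 - y)
        + t_bl * (1 - x) * y
        + t_br * x * y
    )
    pe = p.get("periodic_edges")
    if pe:
        values = values + _periodic_edge_perturbation(
            spec.shape,
            amplitude_k=pe.get("amplitude_k", 1.0),
            period_px=pe.get("period_px", 16.0),
            phase=pe.get("phase", 0.0),
        )
        values = np.clip(values, spec.t_range[0], spec.t_range[1])
    _check_range(values, spec.t_range, "plate field")
    fld = TemperatureField(
        values=values,
        pitch_um=p.get("pitch_um", 1.0),
        meta={
            "generator": "generate_plate_field",
            "spec": {"kind": spec.kind, "shape": list(spec.shape), **_jsonable(p)},
            "t_range": list(spec.t_range),
        },
    )
    if noise_seed is not None:
        fld = add_temperature_noise(fld, p.get("noise_sigma_k", 0.1), noise_seed)
    return fld


def _build_fixed(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    """Fixed-pixel mask/value arrays from edge conditions and heater sources."""
    rows, cols = spec.shape
    p = spec.params
    fixed = np.zeros(spec.shape, dtype=bool)
    values = np.zeros(spec.shape, dtype=np.float64)

    edges = p.get("edges", {})
    modes: dict[str, str] = {}
    for name in ("top", "bottom", "left", "right"):
        cond = edges.get(name, {"kind": "mirror"})
        modes[name] = cond["kind"]
        if cond["kind"] == "dirichlet":
            val = cond["value"]
            if name == "top":
                sl = (0, slice(None))
            elif name == "bottom":
                sl = (rows - 1, slice(None))
            elif name == "left":
                sl = (slice(None), 0)
            else:
                sl = (slice(None), cols - 1)
            fixed[sl] = True
            values[sl] = val
        elif cond["kind"] != "mirror":
            raise ValueError(f"unknown edge condition {cond['kind']!r}")

    for src in p.get("sources", ()):
        t = float(src["temp"])
        if src["kind"] == "vline":
            c = int(src["col"])
            r0, r1 = int(src.get("row_start", 0)), int(src.get("row_end", rows - 1))
            if not (0 <= c < cols and 0 <= r0 <= r1 < rows):
                raise InvalidGeometryError(f"heater line out of bounds: {src}")
            fixed[r0 : r1 + 1, c] = True
            values[r0 : r1 + 1, c] = t
        elif src["kind"] == "hline":
            r = int(src["row"])
            c0, c1 = int(src.get("col_start", 0)), int(src.get("col_end", cols - 1))
            if not (0 <= r < rows and 0 <= c0 <= c1 < cols):
                raise InvalidGeometryError(f"heater line out of bounds: {src}")
            fixed[r, c0 : c1 + 1] = True
            values[r, c0 : c1 + 1] = t
        elif src["kind"] == "points":
            for (r, c) in src["pixels"]:
                fixed[r, c] = True
                values[r, c] = t
        else:
            raise ValueError(f"unknown source kind {src['kind']!r}")
    return fixed, values, modes


def solve_steady_field(spec: FieldSpec, tol: float = 1e-6) -> TemperatureField:
    """Steady-state heat solve on the 5-point stencil with fixed constraints.

    Dirichlet edges and interior heater lines are held at their stated kelvin
    values; ``mirror`` edges are insulated (zero normal flux). The sparse
    linear system is solved directly, then the discrete interior residual
    ``|4·T[i,j] − T[i±1,j] − T[i,j±1]|`` is asserted below ``tol``.
    """
    if spec.kind != "fd_poisson":
        raise ValueError("spec.kind must be 'fd_poisson'")
    rows, cols = spec.shape
    fixed, fvals, _ = _build_fixed(spec)
    if fixed.any():
        if fvals[fixed].min() < spec.t_range[0] - 1e-9 or fvals[fixed].max() > spec.t_range[1] + 1e-9:
            raise RangeError("boundary/source temperatures outside t_range")

    idx = -np.ones(spec.shape, dtype=np.int64)
    free = ~fixed
    n_free = int(free.sum())
    if n_free == 0:
        values = fvals.copy()
    else:
        idx[free] = np.arange(n_free)
        rows_l: list[int] = []
        cols_l: list[int] = []
        data_l: list[float] = []
        rhs = np.zeros(n_free)
        rr, cc = np.nonzero(free)
        for k, (i, j) in enumerate(zip(rr, cc)):
            deg = 0
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < rows and 0 <= nj < cols):
                    continue  # mirror ghost: neighbour drops out of the stencil
                deg += 1
                if fixed[ni, nj]:
                    rhs[k] += fvals[ni, nj]
                else:
                    rows_l.append(k)
                    cols_l.append(idx[ni, nj])
                    data_l.append(-1.0)
            rows_l.append(k)
            cols_l.append(k)
            data_l.append(float(deg))
        a = sp.csr_matrix((data_l, (rows_l, cols_l)), shape=(n_free, n_free))
        try:
            sol = spla.spsolve(a.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular system
            raise ConvergenceError(np.inf, tol) from exc
        values = fvals.copy()
        values[free] = sol

    res = laplace_residual(values, fixed)
    if res >= tol:
        raise ConvergenceError(res, tol)
    _check_range(values, spec.t_range, "steady-state field")
    return TemperatureField(
        values=values,
        pitch_um=spec.params.get("pitch_um", 1.0),
        meta={
            "generator": "solve_steady_field",
            "spec": {"kind": spec.kind, "shape": list(spec.shape), **_jsonable(spec.params)},
            "t_range": list(spec.t_range),
            "max_residual_k": float(res),
        },
    )


def laplace_residual(values: np.ndarray, fixed: np.ndarray | None = None) -> float:
    """Max |4·T − ΣT_neighbours| over interior pixels that are not constrained."""
    interior = np.zeros(values.shape, dtype=bool)
    interior[1:-1, 1:-1] = True
    if fixed is not None:
        interior &= ~fixed
    if not interior.any():
        return 0.0
    lap = np.abs(
        4 * values[1:-1, 1:-1]
        - values[:-2, 1:-1]
        - values[2:, 1:-1]
        - values[1:-1, :-2]
        - values[1:-1, 2:]
    )
    return float(lap[interior[1:-1, 1:-1]].max())


def generate_field(spec: FieldSpec, noise_seed: int | None = None) -> TemperatureField:
    """Dispatch on ``spec.kind`` to the matching generator/solver."""
    if spec.kind == "pipe_cross_section":
        return generate_pipe_field(spec, noise_seed)
    if spec.kind == "plate_dirichlet":
        return generate_plate_field(spec, noise_seed)
    fld = solve_steady_field(spec)
    if noise_seed is not None:
        fld = add_temperature_noise(fld, spec.params.get("noise_sigma_k", 0.1), noise_seed)
    return fld


def add_temperature_noise(
    field: TemperatureField, sigma_k: float, seed: int
) -> TemperatureField:
    """Add i.i.d. pixelwise Gaussian temperature noise of std ``sigma_k``.

    Applied to the temperature field itself, before any conversion to
    fluorescent intensities. Returns a new field; the input is untouched.
    """
    if sigma_k < 0:
        raise ValueError(f"sigma_k must be >= 0, got {sigma_k}")
    rng = np.random.default_rng(seed)
    noisy = field.values + rng.normal(0.0, sigma_k, size=field.shape)
    return field.with_values(noisy, noise={"sigma_k": sigma_k, "seed": int(seed)})


def _jsonable(obj: Any) -> Any:
    """Best-effort conversion of parameter records for JSON sidecars."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
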
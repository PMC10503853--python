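"""Training loops, metrics and the three benchmark experiments.

The experiments mirror the evaluation protocol of the method:

1. *In-range reconstruction*: train the patch networks and the pointwise
   polynomial baseline on noisy five-band images of 298–308 K heat-diffusion
   fields and compare reconstruction RMSE.
2. *Extrapolation*: apply the same trained models to scenes whose temperature
   range (298–312 K) exceeds the training range.
3. *Chip range sweep*: train on masked serpentine-chip scenes (290–380 K
   regime) and measure mask-aware RMSE as a function of the scene temperature
   span, together with the correlation between per-pixel error and the L2
   norm of the temperature gradient.

Training uses mean-squared error on kelvin targets with Adam and image-level
train/validation splits (patches from one image never appear on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Callable, Sequence

import numpy as np
import scipy.stats

from .fieldgen import FieldSpec, TemperatureField
from .models.baselines import mvpf_fit, mvpf_predict
from .models.recurrent import NetConfig, build_model
from .models.nn import Adam
from .patches import SequenceBatch, TileBatch, extract_sequences, extract_tiles, stitch
from .photophysics import CalibrationModel, FluorescentImage
from .presets import (
    DROPPED_CHANNEL,
    dataset1_calibration,
    dataset2_calibration,
    make_dataset1,
)
from .device_sim import build_chip_series

__all__ = [
    "TrainingError",
    "TrainConfig",
    "TrainedModel",
    "ReconstructionResult",
    "ExperimentSpec",
    "ChipSweepSpec",
    "train",
    "rmse",
    "reconstruct",
    "gradient_norm_map",
    "error_gradient_analysis",
    "run_benchmark_experiment",
    "extrapolation_experiment",
    "range_sweep_experiment",
    "run_chip_sweep",
]


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Optimization hyperparameters (none are dictated by the method itself)."""

    epochs: int = 30
    batch_size: int = 256
    lr: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (annealed to lr_min)
    lr_min: float = 1e-4
    patience: int = 10
    seed: int = 0
    center_targets: bool = False


@dataclass
class TrainedModel:
    """A fitted network plus its training lineage."""

    model: Any
    config: NetConfig
    train_loss: list[float] = dc_field(default_factory=list)
    val_rmse: list[float] = dc_field(default_factory=list)
    best_epoch: int = -1
    target_offset: float = 0.0

    def predict(self, inputs: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        return self.model.predict(inputs, batch_size=batch_size) + self.target_offset


def _batch_arrays(
    batch: SequenceBatch | TileBatch,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if batch.targets is None:
        raise ValueError("training batch must carry kelvin targets")
    return batch.inputs, batch.targets, batch.weights


def train(
    config: NetConfig,
    train_batch: SequenceBatch | TileBatch,
    val_batch: SequenceBatch | TileBatch,
    hp: TrainConfig | None = None,
) -> TrainedModel:
    """Fit a patch network with Adam on MSE, early-stopping on validation RMSE.

    The head bias is initialized to the mean training target (equivalently, a
    kelvin offset), so optimization starts from the best constant predictor;
    with ``center_targets`` the offset is removed from the targets instead and
    added back at prediction time.
    """
    hp = hp or TrainConfig()
    x, y, w = _batch_arrays(train_batch)
    xv, yv, wv = _batch_arrays(val_batch)
    model = build_model(config)
    offset = 0.0
    y_mean = float(np.average(y, weights=w) if w is not None else y.mean())
    if hp.center_targets:
        offset = y_mean
        y = y - offset
        yv = yv - offset
    else:
        model.head.b.value[...] = y_mean
    tm = TrainedModel(model=model, config=config, target_offset=offset)

    opt = Adam(model.parameters(), lr=hp.lr)
    rng = np.random.default_rng(hp.seed)
    n = len(x)
    best_state = model.get_state()
    best_val = np.inf
    bad_epochs = 0
    for epoch in range(hp.epochs):
        if hp.lr_schedule == "cosine":
            frac = epoch / max(1, hp.epochs - 1)
            opt.lr = hp.lr_min + 0.5 * (hp.lr - hp.lr_min) * (1 + np.cos(np.pi * frac))
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = perm[start : start + hp.batch_size]
            pred = model.forward(x[idx], training=True)
            err = pred - y[idx]
            if w is None:
                loss = float(np.mean(err * err))
                dout = 2.0 * err / err.size
            else:
                wb = w[idx]
                wsum = max(float(wb.sum()), 1e-12)
                loss = float(np.sum(wb * err * err) / wsum)
                dout = 2.0 * wb * err / wsum
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            model.backward(dout)
            opt.step()
            opt.zero_grad()
        tm.train_loss.append(float(np.mean(losses)))
        val_pred = model.predict(xv)
        verr = (val_pred - yv) ** 2
        if wv is None:
            v = float(np.sqrt(np.mean(verr)))
        else:
            v = float(np.sqrt(np.sum(wv * verr) / max(float(wv.sum()), 1e-12)))
        tm.val_rmse.append(v)
        if v < best_val - 1e-12:
            best_val = v
            best_state = model.get_state()
            tm.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > hp.patience:
                break
    model.set_state(best_state)
    return tm


def rmse(
    predicted: TemperatureField | np.ndarray,
    truth: TemperatureField | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Root mean squared error in kelvin, optionally restricted to a mask."""
    p = predicted.values if isinstance(predicted, TemperatureField) else np.asarray(predicted)
    t = truth.values if isinstance(truth, TemperatureField) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    err = p - t
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != p.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask selects no pixels")
        err = err[mask]
    return float(np.sqrt(np.mean(err * err)))


@dataclass
class ReconstructionResult:
    """Stitched prediction with its error map and summary metrics."""

    predicted: TemperatureField
    truth: TemperatureField | None = None
    mask: np.ndarray | None = None
    error_map: np.ndarray | None = None
    rmse: float | None = None
    gradient_norm_map: np.ndarray | None = None
    lineage: dict[str, Any] = dc_field(default_factory=dict)


def reconstruct(
    model: TrainedModel | Any,
    image: FluorescentImage | np.ndarray,
    truth: TemperatureField | None = None,
    mask: np.ndarray | None = None,
    stride: int = 1,
    patch_kind: str | None = None,
    pitch_um: float = 1.0,
) -> ReconstructionResult:
    """Patch-predict-stitch a full temperature map from a fluorescent image.

    ``patch_kind`` ("sequences" or "tiles") defaults to the model variant:
    tile models consume 5×5 tiles, sequence models 1×5 runs. Any object with
    a ``predict(inputs)`` method works, which is also how test doubles and
    hard-wired oracles are plugged in.
    """
    if patch_kind is None:
        variant = getattr(getattr(model, "config", None), "variant", "FTLSTM")
        patch_kind = "tiles" if variant == "MFTLSTM" else "sequences"
    if patch_kind == "tiles":
        batch = extract_tiles(image, field=truth, stride=stride)
    elif patch_kind == "sequences":
        batch = extract_sequences(image, field=truth, stride=stride)
    else:
        raise ValueError(f"unknown patch_kind {patch_kind!r}")
    preds = model.predict(batch.inputs)
    shape = image.shape if isinstance(image, FluorescentImage) else np.asarray(image).shape[:2]
    predicted = stitch(preds, batch.origins, shape, pitch_um=pitch_um)
    result = ReconstructionResult(
        predicted=predicted,
        truth=truth,
        mask=mask,
        lineage={"patch_kind": patch_kind, "stride": stride},
    )
    if truth is not None:
        result.error_map = predicted.values - truth.values
        result.rmse = rmse(predicted, truth, mask)
        result.gradient_norm_map = gradient_norm_map(truth)
    return result


def gradient_norm_map(field: TemperatureField) -> np.ndarray:
    """Per-pixel L2 norm of the spatial temperature gradient, in K/μm.

    Central differences in the interior, one-sided at the borders, divided by
    the pixel pitch.
    """
    if min(field.shape) < 2:
        raise ValueError("need at least a 2×2 field for gradients")
    gy, gx = np.gradient(field.values, field.pitch_um)
    return np.hypot(gx, gy)


def error_gradient_analysis(result: ReconstructionResult) -> dict[str, Any]:
    """Relate reconstruction error to the local temperature gradient.

    Returns the mean/max gradient norm over the evaluated pixels, the paired
    (|error|, gradient norm) samples, and their Spearman rank correlation
    (flagged undefined when either quantity is constant).
    """
    if result.error_map is None or result.gradient_norm_map is None:
        raise ValueError("result must carry a truth-based error map")
    err = np.abs(result.error_map)
    grad = result.gradient_norm_map
    if result.mask is not None:
        err = err[result.mask]
        grad = grad[result.mask]
    else:
        err = err.ravel()
        grad = grad.ravel()
    out: dict[str, Any] = {
        "mean_gradient_norm": float(grad.mean()),
        "max_gradient_norm": float(grad.max()),
        "pairs": np.stack([err, grad], axis=1),
    }
    if np.ptp(err) == 0 or np.ptp(grad) == 0:
        out["spearman_rho"] = None
        out["correlation_defined"] = False
    else:
        rho = scipy.stats.spearmanr(err, grad).statistic
        out["spearman_rho"] = float(rho)
        out["correlation_defined"] = True
    return out


# --------------------------------------------------------------------------
# Experiment 1 + 2: five-band benchmark with extrapolation
# --------------------------------------------------------------------------


@dataclass
class ExperimentSpec:
    """Study conditions for the five-band benchmark (scaled for one CPU)."""

    train_t_range: tuple[float, float] = (298.0, 308.0)
    test_t_range: tuple[float, float] = (298.0, 312.0)
    image_shape: tuple[int, int] = (32, 32)
    n_train_images: int = 40
    n_val_images: int = 8
    noise_sigma_k: float = 0.1
    stride: int = 1
    variants: tuple[str, ...] = ("FTLSTM", "BFTLSTM", "MFTLSTM")
    include_mvpf: bool = True
    hidden1: int = 48
    hidden2: int = 24
    dropout: float = 0.2
    epochs: int = 40
    epochs_by_variant: dict[str, int] = dc_field(
        default_factory=lambda: {"FTLSTM": 50}  # the cheapest model can afford more
    )
    batch_size: int = 32
    lr: float = 3e-3
    lr_schedule: str = "cosine"
    patience: int = 15
    max_train_sequences: int = 12000
    max_train_tiles: int = 6000
    max_val_patches: int = 1500
    max_train_pixels: int = 20000
    seed: int = 0


def _test_specs(
    shape: tuple[int, int], t_lo: float, t_hi: float
) -> list[FieldSpec]:
    """Fixed evaluation scenes: two pipe cross-sections and one plate map.

    The pipe scenes carry the sinusoidal boundary perturbation, recreating
    the periodic top/bottom edge features that are hardest to reconstruct.
    """
    rows, cols = shape
    m = min(rows, cols)
    t_range = (t_lo, t_hi)
    pe = {"amplitude_k": 0.8, "period_px": 16.0, "phase": 0.0}
    return [
        FieldSpec(
            "pipe_cross_section",
            shape,
            {
                "r_inner": 0.15 * m,
                "r_outer": 0.62 * m,
                "t_inner": t_hi - 0.8,  # headroom for the edge perturbation
                "t_outer": t_lo + 0.8,
                "periodic_edges": pe,
            },
            t_range,
        ),
        FieldSpec(
            "pipe_cross_section",
            shape,
            {
                "r_inner": 0.2 * m,
                "r_outer": 0.55 * m,
                "t_inner": t_lo + 0.8,
                "t_outer": t_hi - 0.8,
                "center": (0.4 * rows, 0.6 * cols),
                "periodic_edges": pe,
            },
            t_range,
        ),
        FieldSpec(
            "plate_dirichlet",
            shape,
            {"corners": [t_lo, 0.5 * (t_lo + t_hi), t_hi, 0.3 * t_lo + 0.7 * t_hi]},
            t_range,
        ),
    ]


def _subsample(rng: np.random.Generator, n: int, cap: int) -> np.ndarray:
    if n <= cap:
        return np.arange(n)
    return rng.choice(n, size=cap, replace=False)


def _pooled_recon_rmse(
    model: Any, pairs: Sequence[tuple[TemperatureField, FluorescentImage]]
) -> float:
    sq, count = 0.0, 0
    for fld, img in pairs:
        res = reconstruct(model, img, truth=fld)
        sq += res.rmse**2 * fld.values.size
        count += fld.values.size
    return float(np.sqrt(sq / count))


def run_benchmark_experiment(
    spec: ExperimentSpec | None = None,
    cal: CalibrationModel | None = None,
    progress: Callable[[str], None] | None = None,
) -> dict[str, Any]:
    """Train the networks and the MVPF baseline; evaluate in- and out-of-range.

    Returns per-model patch-level validation RMSE, pooled reconstruction RMSE
    on held-out in-range scenes, and pooled RMSE on scenes spanning the wider
    test range (extrapolation).
    """
    spec = spec or ExperimentSpec()
    say = progress or (lambda _msg: None)
    if cal is None:
        lo = min(spec.train_t_range[0], spec.test_t_range[0]) - 2.0
        hi = max(spec.train_t_range[1], spec.test_t_range[1]) + 2.0
        cal = dataset1_calibration(lo, hi)
    rng = np.random.default_rng(spec.seed)

    say("generating training/validation images")
    train_pairs = make_dataset1(
        spec.n_train_images,
        cal,
        seed=spec.seed,
        shape=spec.image_shape,
        t_range=spec.train_t_range,
        noise_sigma_k=spec.noise_sigma_k,
    )
    val_pairs = make_dataset1(
        spec.n_val_images,
        cal,
        seed=spec.seed + 10_000,
        shape=spec.image_shape,
        t_range=spec.train_t_range,
        noise_sigma_k=spec.noise_sigma_k,
    )
    test_in = [
        (s, make_dataset1(1, cal, seed=spec.seed + 20_000 + i, specs=[s],
                          noise_sigma_k=spec.noise_sigma_k)[0])
        for i, s in enumerate(_test_specs(spec.image_shape, *spec.train_t_range))
    ]
    test_in_pairs = [pair for _, pair in test_in]
    test_ext_pairs = [
        make_dataset1(1, cal, seed=spec.seed + 30_000 + i, specs=[s],
                      noise_sigma_k=spec.noise_sigma_k)[0]
        for i, s in enumerate(_test_specs(spec.image_shape, *spec.test_t_range))
    ]

    def gather(kind: str, pairs, cap):
        extractor = extract_tiles if kind == "tiles" else extract_sequences
        ins, tgts = [], []
        for fld, img in pairs:
            b = extractor(img, field=fld, stride=spec.stride)
            ins.append(b.inputs)
            tgts.append(b.targets)
        inputs = np.concatenate(ins)
        targets = np.concatenate(tgts)
        keep = _subsample(rng, len(inputs), cap)
        cls = TileBatch if kind == "tiles" else SequenceBatch
        return cls(inputs=inputs[keep], origins=np.zeros((len(keep), 2), int),
                   targets=targets[keep])

    results: dict[str, Any] = {"spec": spec, "models": {}}
    for variant in spec.variants:
        kind = "tiles" if variant == "MFTLSTM" else "sequences"
        cap = spec.max_train_tiles if kind == "tiles" else spec.max_train_sequences
        tb = gather(kind, train_pairs, cap)
        vb = gather(kind, val_pairs, spec.max_val_patches)
        cfg = NetConfig(
            channels_in=tb.inputs.shape[-1],
            variant=variant,
            hidden1=spec.hidden1,
            hidden2=spec.hidden2,
            dropout=spec.dropout,
            seed=spec.seed,
        )
        say(f"training {variant} on {len(tb)} patches")
        epochs = spec.epochs_by_variant.get(variant, spec.epochs)
        tm = train(
            cfg,
            tb,
            vb,
            TrainConfig(
                epochs=epochs,
                batch_size=spec.batch_size,
                lr=spec.lr,
                lr_schedule=spec.lr_schedule,
                patience=spec.patience,
                seed=spec.seed + 1,
            ),
        )
        results["models"][variant] = {
            "trained": tm,
            "val_rmse": min(tm.val_rmse),
            "recon_rmse_in": _pooled_recon_rmse(tm, test_in_pairs),
            "recon_rmse_ext": _pooled_recon_rmse(tm, test_ext_pairs),
        }
        say(f"{variant}: val {results['models'][variant]['val_rmse']:.4f} K, "
            f"recon {results['models'][variant]['recon_rmse_in']:.4f} K, "
            f"extrap {results['models'][variant]['recon_rmse_ext']:.4f} K")

    if spec.include_mvpf:
        xs, ys = [], []
        for fld, img in train_pairs:
            xs.append(img.as_array().reshape(-1, img.n_channels) / 65535.0)
            ys.append(fld.values.ravel())
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        keep = _subsample(rng, len(x), spec.max_train_pixels)
        predictor = mvpf_fit(x[keep], y[keep])

        def pooled_mvpf(pairs):
            sq, count = 0.0, 0
            for fld, img in pairs:
                pred = mvpf_predict(predictor, img)
                sq += rmse(pred, fld) ** 2 * fld.values.size
                count += fld.values.size
            return float(np.sqrt(sq / count))

        results["models"]["MVPF"] = {
            "predictor": predictor,
            "recon_rmse_in": pooled_mvpf(test_in_pairs),
            "recon_rmse_ext": pooled_mvpf(test_ext_pairs),
        }
        say(f"MVPF: recon {results['models']['MVPF']['recon_rmse_in']:.4f} K, "
            f"extrap {results['models']['MVPF']['recon_rmse_ext']:.4f} K")
    return results


def extrapolation_experiment(
    spec: ExperimentSpec | None = None, **kwargs: Any
) -> dict[str, Any]:
    """Alias of the benchmark run emphasizing its paired in/out-of-range RMSEs."""
    return run_benchmark_experiment(spec, **kwargs)


# --------------------------------------------------------------------------
# Experiment 3: chip range sweep with gradient-conditioned error analysis
# --------------------------------------------------------------------------


@dataclass
class ChipSweepSpec:
    """Study conditions for the serpentine-chip range sweep."""

    heater_offsets_k: tuple[float, ...] = (1.0, 5.0, 12.0, 25.0, 50.0)
    shape: tuple[int, int] = (48, 48)
    ambient_k: float = 293.0
    n_passes: int = 4
    channel_width_px: int = 7
    noise_sigma_k: float = 0.1
    n_noise_reps: int = 4
    n_eval_reps: int = 3
    drop_channel: bool = True
    variant: str = "MFTLSTM"
    hidden1: int = 64
    hidden2: int = 32
    # head-feature dropout shrinks predictions at the extremes of the target
    # range, biasing the coldest scenes; replicate augmentation regularizes
    # instead, so this experiment trains without dropout
    dropout: float = 0.0
    epochs: int = 50
    batch_size: int = 32
    lr: float = 3e-3
    lr_schedule: str = "cosine"
    patience: int = 12
    max_train_tiles: int = 5000
    max_val_tiles: int = 1000
    seed: int = 0


def _chip_tiles(
    series: Sequence[tuple[Any, FluorescentImage]], stride: int = 1
) -> TileBatch:
    """Tiles touching the fluorescent channel, loss-weighted by mask membership.

    Pixels outside the channel carry zero counts and no information about the
    local temperature, so they get zero loss weight; the fit is judged only on
    pixels where fluorescence exists, mirroring mask-aware evaluation.
    """
    ins, tgts, wts = [], [], []
    for scene, img in series:
        b = extract_tiles(img, field=scene.field, stride=stride)
        mb = extract_tiles(scene.mask.astype(float) * 65535.0, stride=stride)
        mask_w = mb.inputs[..., 0]
        touch = mask_w.sum(axis=(1, 2)) > 0
        ins.append(b.inputs[touch])
        tgts.append(b.targets[touch])
        wts.append(mask_w[touch])
    return TileBatch(
        inputs=np.concatenate(ins),
        origins=np.zeros((sum(len(i) for i in ins), 2), int),
        targets=np.concatenate(tgts),
        weights=np.concatenate(wts),
    )


def range_sweep_experiment(
    series: Sequence[tuple[Any, FluorescentImage]],
    model: TrainedModel | Any,
) -> list[dict[str, Any]]:
    """Mask-aware RMSE per chip scene, sorted by scene temperature span."""
    if len(series) < 2:
        raise ValueError("need at least 2 scenes")
    rows = []
    for scene, img in series:
        res = reconstruct(model, img, truth=scene.field, mask=scene.mask)
        ana = error_gradient_analysis(res)
        rows.append(
            {
                "span_k": float(np.ptp(scene.field.values)),
                "rmse_k": res.rmse,
                "mean_gradient_norm": ana["mean_gradient_norm"],
                "max_gradient_norm": ana["max_gradient_norm"],
                "pairs": ana["pairs"],
            }
        )
    rows.sort(key=lambda r: r["span_k"])
    return rows


def run_chip_sweep(
    spec: ChipSweepSpec | None = None,
    progress: Callable[[str], None] | None = None,
) -> dict[str, Any]:
    """Train a tile network on the chip series and sweep RMSE vs scene span."""
    spec = spec or ChipSweepSpec()
    say = progress or (lambda _msg: None)
    cal = dataset2_calibration()
    say("building chip series")
    common = dict(
        shape=spec.shape,
        ambient_k=spec.ambient_k,
        n_passes=spec.n_passes,
        channel_width_px=spec.channel_width_px,
        noise_sigma_k=spec.noise_sigma_k,
    )
    # several noise realizations of the same (deterministic) fields: fresh
    # camera exposures of the same steady state, multiplying training tiles
    train_series = [
        pair
        for rep in range(spec.n_noise_reps)
        for pair in build_chip_series(
            spec.heater_offsets_k, cal, seed=spec.seed + 100 * rep, **common
        )
    ]
    eval_reps = [
        build_chip_series(
            spec.heater_offsets_k, cal, seed=spec.seed + 77_000 + 1000 * rep, **common
        )
        for rep in range(spec.n_eval_reps)
    ]
    if spec.drop_channel:
        keep = [n for n in cal.channel_names if n != DROPPED_CHANNEL]
        train_series = [(s, img.select_channels(keep)) for s, img in train_series]
        eval_reps = [
            [(s, img.select_channels(keep)) for s, img in series]
            for series in eval_reps
        ]
    eval_series = eval_reps[0]

    tb = _chip_tiles(train_series)
    vb = _chip_tiles(eval_series)
    rng = np.random.default_rng(spec.seed)
    keep_t = _subsample(rng, len(tb), spec.max_train_tiles)
    keep_v = _subsample(rng, len(vb), spec.max_val_tiles)
    tb = TileBatch(tb.inputs[keep_t], tb.origins[keep_t], tb.targets[keep_t],
                   tb.weights[keep_t])
    vb = TileBatch(vb.inputs[keep_v], vb.origins[keep_v], vb.targets[keep_v],
                   vb.weights[keep_v])

    cfg = NetConfig(
        channels_in=tb.inputs.shape[-1],
        variant=spec.variant,
        hidden1=spec.hidden1,
        hidden2=spec.hidden2,
        dropout=spec.dropout,
        seed=spec.seed,
    )
    say(f"training {spec.variant} on {len(tb)} chip tiles")
    tm = train(
        cfg,
        tb,
        vb,
        TrainConfig(
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            lr=spec.lr,
            lr_schedule=spec.lr_schedule,
            patience=spec.patience,
            seed=spec.seed + 1,
        ),
    )
    # average the per-scene squared error over several fresh noise
    # realizations (repeat exposures of the same steady state)
    rep_sweeps = [range_sweep_experiment(series, tm) for series in eval_reps]
    sweep = []
    for rows in zip(*rep_sweeps):
        agg = dict(rows[0])
        agg["rmse_k"] = float(np.sqrt(np.mean([r["rmse_k"] ** 2 for r in rows])))
        agg["pairs"] = np.concatenate([r["pairs"] for r in rows])
        sweep.append(agg)
    pairs = np.concatenate([row.pop("pairs") for row in sweep])
    if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
        rho = None
    else:
        rho = float(scipy.stats.spearmanr(pairs[:, 0], pairs[:, 1]).statistic)
    say(f"sweep spans {[round(r['span_k'], 2) for r in sweep]} K, "
        f"rmse {[round(r['rmse_k'], 4) for r in sweep]} K, spearman {rho}")
    return {
        "spec": spec,
        "trained": tm,
        "val_rmse": min(tm.val_rmse),
        "sweep": sweep,
        "error_gradient_spearman": rho,
    }
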
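"""Metrics, training loop mechanics, reconstruction plumbing and gradient analysis."""

import numpy as np
import pytest

from fluorotherm.fieldgen import FieldSpec, TemperatureField, generate_plate_field
from fluorotherm.harness import (
    ReconstructionResult,
    TrainConfig,
    error_gradient_analysis,
    gradient_norm_map,
    rmse,
    reconstruct,
    train,
)
from fluorotherm.models.recurrent import NetConfig
from fluorotherm.patches import SequenceBatch, extract_tiles
from fluorotherm.photophysics import render_image


class TestRmse:
    def test_identical_fields_have_zero_error(self):
        a = TemperatureField(np.full((6, 6), 300.0))
        assert rmse(a, a) == 0.0

    def test_constant_offset_gives_that_offset(self):
        a = np.full((5, 5), 300.0)
        assert rmse(a + 0.3, a) == pytest.approx(0.3)

    def test_alternating_errors_average_in_quadrature(self):
        truth = np.zeros((2, 2))
        pred = np.array([[0.1, -0.1], [0.1, -0.1]])
        assert rmse(pred, truth) == pytest.approx(0.1)

    def test_mask_restriction_equals_masked_computation(self, rng):
        truth = rng.normal(size=(10, 10))
        pred = truth + rng.normal(size=(10, 10)) * 0.2
        mask = rng.random((10, 10)) > 0.5
        direct = np.sqrt(np.mean((pred - truth)[mask] ** 2))
        assert rmse(pred, truth, mask) == pytest.approx(direct)

    def test_triangle_inequality_bound(self, rng):
        a, b, c = (rng.normal(size=(8, 8)) for _ in range(3))
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12

    def test_shape_mismatch_and_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty mask"):
            rmse(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2), bool))


class TestGradientNormMap:
    def test_uniform_field_has_zero_gradient(self):
        fld = TemperatureField(np.full((6, 6), 305.0))
        assert np.all(gradient_norm_map(fld) == 0.0)

    def test_linear_ramp_gradient_in_kelvin_per_micron(self):
        fld = TemperatureField(np.tile(0.5 * np.arange(8), (6, 1)), pitch_um=1.0)
        g = gradient_norm_map(fld)
        assert np.allclose(g, 0.5)

    def test_diagonal_ramp_follows_pythagoras(self):
        y, x = np.meshgrid(np.arange(7), np.arange(9), indexing="ij")
        fld = TemperatureField(0.4 * y + 0.3 * x, pitch_um=1.0)
        assert np.allclose(gradient_norm_map(fld), 0.5)

    def test_pitch_rescales_gradient(self):
        vals = np.tile(np.arange(6, dtype=float), (4, 1))
        g1 = gradient_norm_map(TemperatureField(vals, pitch_um=1.0))
        g2 = gradient_norm_map(TemperatureField(vals, pitch_um=2.0))
        assert np.allclose(g1, 2 * g2)

    def test_translation_invariance(self, rng):
        vals = rng.normal(size=(7, 7))
        g1 = gradient_norm_map(TemperatureField(vals))
        g2 = gradient_norm_map(TemperatureField(vals + 42.0))
        np.testing.assert_allclose(g1, g2)


class TestErrorGradientAnalysis:
    def _result(self, err, grad):
        h, w = err.shape
        fld = TemperatureField(np.zeros((h, w)))
        return ReconstructionResult(
            predicted=fld, truth=fld, error_map=err, gradient_norm_map=grad
        )

    def test_error_equal_to_gradient_has_perfect_rank_correlation(self, rng):
        g = rng.random((20, 20))
        out = error_gradient_analysis(self._result(g.copy(), g))
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_shuffled_errors_are_uncorrelated(self, rng):
        g = rng.random((100, 100))
        e = rng.permutation(g.ravel()).reshape(g.shape)
        out = error_gradient_analysis(self._result(e, g))
        assert abs(out["spearman_rho"]) < 0.05

    def test_constant_error_map_flagged_not_crashed(self):
        out = error_gradient_analysis(
            self._result(np.full((5, 5), 0.2), np.random.default_rng(0).random((5, 5)))
        )
        assert out["correlation_defined"] is False
        assert out["spearman_rho"] is None

    def test_summary_reports_mean_and_max_gradient(self, rng):
        g = rng.random((10, 10))
        out = error_gradient_analysis(self._result(rng.random((10, 10)), g))
        assert out["mean_gradient_norm"] == pytest.approx(g.mean())
        assert out["max_gradient_norm"] == pytest.approx(g.max())


class _Oracle:
    """Test double that answers with the stitched ground truth targets."""

    def __init__(self, field, kind):
        self.field = field
        self.kind = kind

    def predict(self, inputs):
        batch = (
            extract_tiles(np.zeros(self.field.shape + (1,)), field=self.field)
            if self.kind == "tiles"
            else None
        )
        return batch.targets[: len(inputs)]


class TestReconstruct:
    def test_perfect_model_reconstructs_exactly(self, cal5):
        spec = FieldSpec(
            "plate_dirichlet", (12, 12),
            {"corners": [299.0, 302.0, 304.0, 307.0]}, (298.0, 308.0),
        )
        fld = generate_plate_field(spec)
        img = render_image(fld, cal5)
        oracle = _Oracle(fld, "tiles")
        res = reconstruct(oracle, img, truth=fld, patch_kind="tiles")
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.error_map.max() == pytest.approx(0.0, abs=1e-12)

    def test_full_coverage_for_any_image_at_least_5x5(self, cal5):
        fld = TemperatureField(np.full((5, 7), 303.0))
        img = render_image(fld, cal5)
        res = reconstruct(_Oracle(fld, "tiles"), img, truth=fld, patch_kind="tiles")
        assert np.all(res.predicted.meta["coverage"] > 0)

    def test_rmse_squares_to_mean_squared_error_map(self, cal5, rng):
        fld = TemperatureField(rng.uniform(299, 307, (9, 9)))
        img = render_image(fld, cal5)

        class Noisy:
            def predict(self, inputs):
                b = extract_tiles(np.zeros((9, 9, 1)), field=fld)
                return b.targets[: len(inputs)] + 0.05

        res = reconstruct(Noisy(), img, truth=fld, patch_kind="tiles")
        assert res.rmse**2 == pytest.approx(np.mean(res.error_map**2))


def _toy_batches(rng, n=256):
    """A learnable toy task: sequence temperature = scaled channel sum."""
    x = rng.uniform(0.0, 1.0, size=(n, 5, 2))
    y = 300.0 + 2.0 * x.sum(axis=2)
    return (
        SequenceBatch(x[: n // 2], np.zeros((n // 2, 2), int), y[: n // 2]),
        SequenceBatch(x[n // 2 :], np.zeros((n // 2, 2), int), y[n // 2 :]),
    )


class TestTrain:
    def test_single_epoch_smoke_contract(self, rng):
        tb, vb = _toy_batches(rng, 20)
        cfg = NetConfig(channels_in=2, variant="FTLSTM", hidden1=8, hidden2=4, seed=0)
        tm = train(cfg, tb, vb, TrainConfig(epochs=1, batch_size=8, seed=0))
        assert len(tm.train_loss) == 1
        assert len(tm.val_rmse) == 1

    def test_loss_descends_on_learnable_toy_task(self, rng):
        tb, vb = _toy_batches(rng)
        cfg = NetConfig(channels_in=2, variant="FTLSTM", hidden1=16, hidden2=8,
                        dropout=0.0, seed=1)
        tm = train(cfg, tb, vb, TrainConfig(epochs=80, batch_size=16, lr=1e-2,
                                            lr_schedule="cosine", patience=80, seed=2))
        assert tm.train_loss[-1] < tm.train_loss[0]
        assert min(tm.val_rmse) < 0.3 * tm.val_rmse[0]

    def test_identical_seeds_reproduce_the_loss_curve(self, rng):
        tb, vb = _toy_batches(rng, 64)
        cfg = NetConfig(channels_in=2, variant="BFTLSTM", hidden1=8, hidden2=4, seed=5)
        hp = TrainConfig(epochs=3, batch_size=16, seed=9)
        a = train(cfg, tb, vb, hp)
        b = train(cfg, tb, vb, hp)
        assert a.train_loss == b.train_loss
        assert a.val_rmse == b.val_rmse

    def test_divergence_raises_training_error(self, rng):
        from fluorotherm.harness import TrainingError

        tb, vb = _toy_batches(rng, 64)
        tb.targets[0, 0] = np.nan  # a corrupt target makes the loss non-finite
        cfg = NetConfig(channels_in=2, variant="FTLSTM", hidden1=4, hidden2=3, seed=0)
        with pytest.raises(TrainingError):
            train(cfg, tb, vb, TrainConfig(epochs=2, batch_size=16, seed=0))
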
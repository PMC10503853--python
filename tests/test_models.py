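"""Recurrent architectures (gradients, symmetries, parameter counts) and baselines."""

import numpy as np
import pytest

from fluorotherm.models.baselines import mvpf_fit, mvpf_predict, rf_fit, rf_predict
from fluorotherm.models.recurrent import (
    BFTLSTM,
    FTLSTM,
    MFTLSTM,
    NetConfig,
    build_model,
    lstm_param_count,
)


def tiny_cfg(variant, **kw):
    defaults = dict(channels_in=2, hidden1=6, hidden2=4, dropout=0.0, seed=7, dtype="float64")
    defaults.update(kw)
    return NetConfig(variant=variant, **defaults)


class TestShapesAndDeterminism:
    @pytest.mark.parametrize(
        "variant,in_shape,out_shape",
        [
            ("FTLSTM", (9, 5, 2), (9, 5)),
            ("BFTLSTM", (9, 5, 2), (9, 5)),
            ("MFTLSTM", (9, 5, 5, 2), (9, 5, 5)),
        ],
    )
    def test_output_shapes(self, variant, in_shape, out_shape, rng):
        model = build_model(tiny_cfg(variant))
        out = model.forward(rng.normal(size=in_shape))
        assert out.shape == out_shape

    def test_evaluation_mode_is_deterministic_and_batch_order_invariant(self, rng):
        model = build_model(tiny_cfg("BFTLSTM", dropout=0.3))
        x = rng.normal(size=(8, 5, 2))
        a = model.forward(x)
        b = model.forward(x)
        np.testing.assert_array_equal(a, b)
        perm = rng.permutation(8)
        np.testing.assert_allclose(model.forward(x[perm]), a[perm], atol=1e-12)

    def test_dropout_active_only_during_training(self, rng):
        model = build_model(tiny_cfg("FTLSTM", dropout=0.5))
        x = rng.normal(size=(64, 5, 2))
        eval_out = model.forward(x, training=False)
        train_out = model.forward(x, training=True)
        assert not np.allclose(eval_out, train_out)
        # and a nominally zero dropout matches evaluation exactly
        model0 = build_model(tiny_cfg("FTLSTM", dropout=0.0))
        np.testing.assert_array_equal(
            model0.forward(x, training=True), model0.forward(x, training=False)
        )

    def test_bad_input_shapes_rejected(self, rng):
        model = build_model(tiny_cfg("FTLSTM"))
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(4, 6, 2)))
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(4, 5, 3)))


class TestParameterCounts:
    @pytest.mark.parametrize(
        "c,h1,h2",
        [(5, 1024, 612), (5, 16, 8), (2, 7, 3), (6, 64, 32)],
    )
    def test_ftlstm_count_matches_gated_recurrent_formula(self, c, h1, h2):
        model = build_model(NetConfig(channels_in=c, variant="FTLSTM", hidden1=h1, hidden2=h2))
        expected = lstm_param_count(c, h1) + lstm_param_count(h1, h2) + (h2 + 1)
        assert model.param_count() == expected

    def test_default_five_channel_ftlstm_has_8226869_parameters(self):
        model = build_model(NetConfig(channels_in=5, variant="FTLSTM"))
        assert model.param_count() == 8_226_869
        assert lstm_param_count(5, 1024) == 4_218_880
        assert lstm_param_count(1024, 612) == 4_007_376

    def test_bidirectional_doubles_core_parameters(self):
        f = build_model(tiny_cfg("FTLSTM"))
        b = build_model(tiny_cfg("BFTLSTM"))
        head = 4 + 1
        assert b.param_count() - head == 2 * (f.param_count() - head)

    def test_weight_tying_halves_directional_parameters(self):
        untied = build_model(tiny_cfg("BFTLSTM"))
        tied = build_model(tiny_cfg("BFTLSTM", tie_weights=True))
        head = 4 + 1
        assert tied.param_count() - head == (untied.param_count() - head) // 2


class TestGradients:
    @pytest.mark.parametrize("variant,shape", [
        ("FTLSTM", (5, 5, 2)),
        ("BFTLSTM", (5, 5, 2)),
        ("MFTLSTM", (3, 5, 5, 2)),
    ])
    def test_backprop_matches_finite_differences(self, variant, shape, rng):
        model = build_model(tiny_cfg(variant))
        x = rng.normal(size=shape)
        y = rng.normal(size=model.forward(x).shape)
        pred = model.forward(x, training=True)
        model.backward(pred - y)

        def loss():
            p = model.forward(x)
            return 0.5 * np.sum((p - y) ** 2)

        for par in model.parameters():
            idx = np.unravel_index(int(np.argmax(np.abs(par.grad))), par.grad.shape)
            eps = 1e-6
            orig = par.value[idx]
            par.value[idx] = orig + eps
            lp = loss()
            par.value[idx] = orig - eps
            lm = loss()
            par.value[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = par.grad[idx]
            assert abs(numeric - analytic) <= 1e-6 + 1e-4 * (abs(numeric) + abs(analytic))


class TestSymmetries:
    def test_tied_bftlstm_maps_palindromes_to_palindromes(self, rng):
        model = build_model(tiny_cfg("BFTLSTM", tie_weights=True))
        half = rng.normal(size=(6, 2, 2))
        x = np.concatenate([half, rng.normal(size=(6, 1, 2)), half[:, ::-1]], axis=1)
        out = model.forward(x)
        np.testing.assert_array_equal(out, out[:, ::-1])

    def test_untied_bftlstm_breaks_palindrome_symmetry(self, rng):
        model = build_model(tiny_cfg("BFTLSTM", tie_weights=False))
        half = rng.normal(size=(6, 2, 2))
        x = np.concatenate([half, rng.normal(size=(6, 1, 2)), half[:, ::-1]], axis=1)
        out = model.forward(x)
        assert not np.allclose(out, out[:, ::-1])

    def test_tied_mftlstm_commutes_with_tile_transposition(self, rng):
        model = build_model(tiny_cfg("MFTLSTM", tie_weights=True))
        x = rng.normal(size=(6, 5, 5, 2))
        xt = np.swapaxes(x, 1, 2)
        np.testing.assert_array_equal(
            model.forward(xt), np.swapaxes(model.forward(x), 1, 2)
        )

    def test_bftlstm_fusion_aligns_by_source_position(self, rng):
        """Fused feature k must equal fwd-scan(k) + re-reversed rev-scan(k)."""
        cfg = tiny_cfg("BFTLSTM")
        model = build_model(cfg)
        x = rng.normal(size=(3, 5, 2))
        fwd = model.bidir.fwd.forward(x)
        rev = model.bidir.rev.forward(x[:, ::-1])[:, ::-1]
        fused = model.bidir.forward(x)
        np.testing.assert_allclose(fused, fwd + rev, atol=1e-12)

    def test_mftlstm_fuses_row_and_column_features_by_source_pixel(self, rng):
        cfg = tiny_cfg("MFTLSTM")
        model = build_model(cfg)
        x = rng.normal(size=(2, 5, 5, 2))
        row_feat = model.rows.forward(x.reshape(10, 5, 2)).reshape(2, 5, 5, 4)
        col_feat = model.cols.forward(
            np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(10, 5, 2)
        ).reshape(2, 5, 5, 4)
        expected = row_feat + col_feat.transpose(0, 2, 1, 3)
        fused = expected  # feature at (i, j): row scan (i, step j) + column scan (j, step i)
        out = model.forward(x)
        manual = model.head.forward(fused)[..., 0]
        np.testing.assert_allclose(out, manual, atol=1e-12)


class TestMVPF:
    def test_monomial_count_for_five_channels_is_21(self, rng):
        x = rng.uniform(size=(50, 5))
        pred = mvpf_fit(x, x @ np.arange(1.0, 6.0))
        assert pred.n_terms == 21

    def test_exact_degree_two_polynomial_recovered(self, rng):
        x = rng.uniform(size=(60, 3))
        y = 2.0 + x[:, 0] - 3.0 * x[:, 1] * x[:, 2] + 0.5 * x[:, 0] ** 2
        pred = mvpf_fit(x, y)
        x_test = rng.uniform(size=(4, 4, 3))
        img = x_test.reshape(-1, 3)
        expected = 2.0 + img[:, 0] - 3.0 * img[:, 1] * img[:, 2] + 0.5 * img[:, 0] ** 2
        np.testing.assert_allclose(pred.predict(img), expected, atol=1e-8)

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            mvpf_fit(rng.uniform(size=(5, 5)), rng.uniform(size=5))

    def test_image_prediction_reshapes_to_field(self, rng):
        x = rng.uniform(size=(100, 2))
        pred = mvpf_fit(x, 300.0 + x[:, 0])
        img = rng.uniform(0, 65535, size=(6, 7, 2))
        fld = mvpf_predict(pred, img)
        assert fld.shape == (6, 7)


class TestRandomForest:
    def test_constant_target_predicts_constant(self, rng):
        x = rng.uniform(size=(40, 3))
        rf = rf_fit(x, np.full(40, 301.5), n_estimators=10, seed=0)
        assert np.allclose(rf.predict(x), 301.5)

    def test_single_stump_on_separable_clusters_predicts_cluster_means(self):
        x = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([300.0, 301.0, 340.0, 341.0])
        rf = rf_fit(x, y, n_estimators=1, max_depth=1, max_features=1, seed=0)
        preds = rf.predict(np.array([[0.05], [0.95]]))
        # a depth-1 tree on bootstrap data splits the two clusters and
        # predicts each side's (bootstrap) mean, far from the other cluster
        assert abs(preds[0] - 300.5) < 1.1 and abs(preds[1] - 340.5) < 1.1

    def test_noise_degrades_forest_accuracy(self, cal5):
        """Pointwise forests cannot denoise: clean inputs beat noisy inputs."""
        from fluorotherm.fieldgen import FieldSpec, add_temperature_noise, generate_pipe_field
        from fluorotherm.photophysics import render_image

        spec = FieldSpec(
            "pipe_cross_section", (40, 40),
            {"r_inner": 6, "r_outer": 18, "t_inner": 307.0, "t_outer": 299.0},
            (298.0, 308.0),
        )
        clean = generate_pipe_field(spec)
        noisy = add_temperature_noise(clean, 0.1, seed=9)
        img_clean = render_image(clean, cal5)
        img_noisy = render_image(noisy, cal5)

        def fit_eval(img):
            x = img.as_array().reshape(-1, 5) / 65535.0
            y = clean.values.ravel()
            rng = np.random.default_rng(1)
            idx = rng.choice(len(x), 1200, replace=False)
            rf = rf_fit(x[idx], y[idx], n_estimators=30, seed=2)
            pred = rf_predict(rf, img)
            return np.sqrt(np.mean((pred.values - clean.values) ** 2))

        assert fit_eval(img_clean) < fit_eval(img_noisy)
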
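"""Emission model, band integration, calibration, rendering and inversion."""

import numpy as np
import pytest

from fluorotherm.fieldgen import RangeError, TemperatureField
from fluorotherm.photophysics import (
    FilterBand,
    FilterBank,
    FluorescentImage,
    band_integrate,
    bin_pixels,
    emission_spectrum,
    fit_calibration,
    pointwise_invert,
    render_image,
)
from fluorotherm.presets import dataset1_filterbank, dataset2_filterbank, default_qd_model

WL = np.arange(500.0, 750.0, 0.1)


class TestEmissionSpectrum:
    def test_peak_at_reference_temperature(self):
        m = default_qd_model()
        s = emission_spectrum(m, m.t_ref, WL)
        assert WL[np.argmax(s)] == pytest.approx(620.0, abs=0.1)

    def test_peak_redshifts_at_rate_of_tenth_nm_per_kelvin(self):
        m = default_qd_model()
        s = emission_spectrum(m, m.t_ref + 10.0, WL)
        assert WL[np.argmax(s)] == pytest.approx(621.0, abs=0.11)

    def test_room_temperature_peak_near_620nm(self):
        s = emission_spectrum(default_qd_model(), 298.0, WL)
        assert abs(WL[np.argmax(s)] - 620.0) < 1.0

    def test_quenching_reduces_total_area(self):
        m = default_qd_model()
        a_cold = np.trapezoid(emission_spectrum(m, 298.0, WL), WL)
        a_hot = np.trapezoid(emission_spectrum(m, 350.0, WL), WL)
        assert a_hot < a_cold
        assert a_hot == pytest.approx(a_cold * (1 - 0.005 * 52) / 1.0, rel=1e-3)

    def test_out_of_range_temperature_rejected(self):
        with pytest.raises(RangeError):
            emission_spectrum(default_qd_model(), 1000.0, WL)


class TestBandIntegrate:
    def test_identity_filter_recovers_total_area(self):
        m = default_qd_model()
        s = emission_spectrum(m, 300.0, WL)
        bank = FilterBank((FilterBand("all", "band-pass", 625.0, 250.0, 0.0),))
        (val,) = band_integrate(s, WL, bank)
        assert val == pytest.approx(np.trapezoid(s, WL), rel=1e-12)

    def test_disjoint_sharp_bands_are_additive(self):
        m = default_qd_model()
        s = emission_spectrum(m, 305.0, WL)
        lo = FilterBand("lo", "band-pass", 560.0, 120.0, 0.0)  # 500-620
        hi = FilterBand("hi", "band-pass", 685.0, 130.0, 0.0)  # 620-750
        both = FilterBand("both", "band-pass", 625.0, 250.0, 0.0)
        parts = band_integrate(s, WL, FilterBank((lo, hi)))
        (whole,) = band_integrate(s, WL, FilterBank((both,)))
        # the shared edge wavelength is counted in both parts: tolerance is one grid cell
        assert parts.sum() == pytest.approx(whole, rel=1e-3)

    def test_homogeneous_in_spectrum_amplitude(self):
        s = emission_spectrum(default_qd_model(), 300.0, WL)
        bank = dataset1_filterbank()
        np.testing.assert_allclose(
            band_integrate(3.5 * s, WL, bank), 3.5 * band_integrate(s, WL, bank)
        )

    def test_no_overlap_warns_and_returns_zero(self):
        s = np.ones_like(WL)
        bank = FilterBank((FilterBand("uv", "band-pass", 300.0, 20.0, 0.0),))
        with pytest.warns(UserWarning, match="no overlap"):
            (val,) = band_integrate(s, WL, bank)
        assert val == 0.0

    def test_soft_edges_overlap_while_sharp_edges_do_not(self):
        sharp = dataset1_filterbank()
        soft = dataset2_filterbank()
        sharp_t = np.stack([b.transmission(WL) for b in sharp.bands])
        soft_t = np.stack([b.transmission(WL) for b in soft.bands])
        # sharp five-band set tiles the support: no wavelength in two bands
        assert (np.sort(sharp_t, axis=0)[-2] > 0).sum() == 0
        # filter-wheel bands genuinely overlap
        assert (np.sort(soft_t, axis=0)[-2] > 0.5).sum() > 0


class TestFitCalibration:
    def test_exact_quadratic_data_recovered(self):
        t = np.linspace(298, 308, 11)
        raw = np.stack([2.0 * t**2 - 3.0 * t + 10.0, 0.5 * t**2 + t], axis=1)
        cal = fit_calibration(t, raw)
        scaled = cal.scale_raw(raw)
        pred = cal.predict_counts(t)
        assert np.abs(pred - scaled).max() < 1e-6

    def test_scaling_anchors_map_extremes_to_grayscale_limits(self, cal5):
        lo, hi = cal5.scale_anchors
        assert cal5.scale_raw(np.array([lo, hi])) == pytest.approx([0.0, 65535.0])

    @pytest.mark.filterwarnings("ignore:calibration channel")
    def test_three_points_interpolated_exactly(self):
        t = np.array([298.0, 303.0, 308.0])
        raw = np.array([[10.0], [45.0], [20.0]])
        cal = fit_calibration(t, raw)
        pred = cal.predict_counts(t)[:, 0]
        np.testing.assert_allclose(pred, cal.scale_raw(raw)[:, 0], atol=1e-6)

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration([300.0, 301.0], np.ones((2, 2)))


class TestRenderInvert:
    def test_uniform_field_renders_uniform_channels(self, cal5):
        fld = TemperatureField(np.full((8, 8), 303.0))
        img = render_image(fld, cal5)
        for ch in img.channels:
            assert np.all(ch == ch[0, 0])

    def test_five_band_calibration_gives_five_channels(self, pipe_field, cal5):
        assert render_image(pipe_field, cal5).n_channels == 5

    def test_rendering_is_monotone_where_calibration_is(self, cal5):
        t = np.linspace(*cal5.t_range, 50)
        counts = cal5.predict_counts(t)
        for ch in range(cal5.n_channels):
            if cal5.monotone[ch]:
                d = np.diff(counts[:, ch])
                assert np.all(d > 0) or np.all(d < 0)

    def test_roundtrip_identity_unquantized(self, pipe_field, cal5):
        img = render_image(pipe_field, cal5, quantize=False)
        rec = pointwise_invert(img, cal5)
        assert np.abs(rec.values - pipe_field.values).max() < 1e-6

    def test_quantized_roundtrip_error_bounded_by_sensitivity(self, pipe_field, cal5):
        img = render_image(pipe_field, cal5, quantize=True)
        rec = pointwise_invert(img, cal5)
        t = np.linspace(*cal5.t_range, 200)
        slopes = np.abs(2 * cal5.coeffs[:, 0] * t[:, None] + cal5.coeffs[:, 1])
        bound = 1.0 / slopes[:, cal5.monotone].min()
        assert np.abs(rec.values - pipe_field.values).max() <= bound

    def test_noise_passes_through_inversion_at_unit_gain(self, cal5):
        from fluorotherm.fieldgen import add_temperature_noise

        clean = TemperatureField(np.full((80, 80), 303.0))
        noisy = add_temperature_noise(clean, 0.1, seed=21)
        img = render_image(noisy, cal5, quantize=False)
        rec = pointwise_invert(img, cal5)
        err = np.sqrt(np.mean((rec.values - clean.values) ** 2))
        assert err == pytest.approx(0.1, rel=0.2)

    def test_out_of_range_pixel_names_location(self, cal5):
        vals = np.full((4, 4), 303.0)
        vals[2, 1] = 350.0
        with pytest.raises(RangeError, match=r"\(2, 1\)"):
            render_image(TemperatureField(vals), cal5)


class TestBinPixels:
    def test_factor_one_is_identity(self, pipe_field, cal5):
        img = render_image(pipe_field, cal5)
        out = bin_pixels(img, 1)
        np.testing.assert_array_equal(out.channels, img.channels)

    def test_four_by_four_block_mean_with_round_half_even(self):
        block = np.arange(1.0, 17.0).reshape(1, 4, 4)
        img = FluorescentImage(channels=block, meta={"quantized": True})
        out = bin_pixels(img, 4)
        assert out.channels.shape == (1, 1, 1)
        assert out.channels[0, 0, 0] == 8.0  # mean 8.5 rounds half-to-even

    def test_trailing_remainder_cropped_and_logged(self, cal5):
        fld = TemperatureField(np.full((10, 10), 300.0))
        out = bin_pixels(render_image(fld, cal5), 4)
        assert out.shape == (2, 2)
        assert out.meta["binning"]["cropped"] == [2, 2]

    def test_binning_commutes_with_rendering_blockwise_constant_fields(self, cal5):
        rng = np.random.default_rng(0)
        coarse = rng.uniform(299, 307, size=(3, 3))
        fine = np.kron(coarse, np.ones((4, 4)))
        binned = bin_pixels(render_image(TemperatureField(fine), cal5, quantize=False), 4)
        direct = render_image(TemperatureField(coarse), cal5, quantize=False)
        np.testing.assert_allclose(binned.channels, direct.channels, atol=1e-9)

    def test_bad_factor_rejected(self, pipe_field, cal5):
        with pytest.raises(ValueError):
            bin_pixels(render_image(pipe_field, cal5), 0)
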
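import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import raman_dbc as rd
from raman_dbc.preprocess import _lower_hull_indices

from _oracles import brute_lower_hull, brute_savgol


def spec(y, w=None):
    y = np.asarray(y, float)
    if w is None:
        w = np.arange(y.size, dtype=float)
    return rd.Spectrum(w, y)


class TestSNV:
    def test_three_point_analytic_case(self):
        out = rd.snv_normalize(spec([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensities, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self, random_spectrum):
        once = rd.snv_normalize(random_spectrum)
        twice = rd.snv_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_output_moments_match_direct_computation(self, random_spectrum):
        out = rd.snv_normalize(random_spectrum).intensities
        assert abs(out.mean()) < 1e-12
        assert abs(np.std(out, ddof=1) - 1.0) < 1e-12

    def test_constant_spectrum_rejected(self):
        with pytest.raises(rd.DegenerateSpectrumError):
            rd.snv_normalize(spec([5.0, 5.0, 5.0]))

    @given(a=st.floats(0.01, 100.0), b=st.floats(-100.0, 100.0))
    def test_invariant_to_multiplicative_scatter(self, a, b):
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 3.0, 64)
        base = rd.snv_normalize(spec(y)).intensities
        shifted = rd.snv_normalize(spec(a * y + b)).intensities
        np.testing.assert_allclose(shifted, base, rtol=1e-10, atol=1e-10)


class TestSavgol:
    def test_reproduces_quadratic_with_zero_derivative(self):
        w = np.arange(100.0)
        s = spec(w**2, w)
        out = rd.savgol_filter(s, 11, 2, 0)
        np.testing.assert_allclose(out.intensities[5:-5], s.intensities[5:-5], atol=1e-8)

    def test_line_slope_per_wavenumber(self):
        # spacing 0.5 cm^-1: the derivative must come out per cm^-1, not per index
        w = 600.0 + 0.5 * np.arange(200)
        out = rd.savgol_filter(spec(3.0 * w + 7.0, w), 15, 1, 1)
        np.testing.assert_allclose(out.intensities[7:-7], 3.0, atol=1e-9)

    @pytest.mark.parametrize("window,poly,deriv", [(15, 1, 1), (25, 2, 2), (27, 2, 0)])
    def test_matches_brute_force_window_fits(self, random_spectrum, window, poly, deriv):
        out = rd.savgol_filter(random_spectrum, window, poly, deriv)
        ref = brute_savgol(
            random_spectrum.wavenumbers, random_spectrum.intensities, window, poly, deriv
        )
        h = window // 2
        np.testing.assert_allclose(out.intensities[h:-h], ref[h:-h], rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize(
        "window,poly,deriv", [(14, 2, 1), (5, 4, 1), (15, 1, 2), (1001, 2, 1)]
    )
    def test_invalid_parameters_rejected(self, random_spectrum, window, poly, deriv):
        with pytest.raises(rd.SpectrumError):
            rd.savgol_filter(random_spectrum, window, poly, deriv)

    def test_nonuniform_axis_requires_resampling(self, rng):
        w = np.sort(rng.uniform(600.0, 700.0, 80))
        s = rd.Spectrum(w, rng.normal(size=80))
        with pytest.raises(rd.NonUniformAxisError, match="resample"):
            rd.savgol_filter(s, 15, 1, 1)
        resampled = rd.resample_uniform(s)
        assert resampled.is_uniform()
        rd.savgol_filter(resampled, 15, 1, 1)  # now valid


class TestRubberband:
    def test_linear_spectrum_is_its_own_baseline(self):
        w = np.arange(50.0)
        base, corr = rd.rubberband_baseline(spec(2.0 * w + 1.0, w))
        np.testing.assert_allclose(base.intensities, 2.0 * w + 1.0, atol=1e-12)
        np.testing.assert_allclose(corr.intensities, 0.0, atol=1e-12)

    def test_peak_on_flat_zero_background_unchanged(self):
        w = np.arange(200.0)
        y = 5.0 * np.exp(-0.5 * ((w - 100.0) / 8.0) ** 2)
        _, corr = rd.rubberband_baseline(spec(y, w))
        np.testing.assert_allclose(corr.intensities, y, atol=1e-12)

    def test_hull_matches_quadratic_brute_force(self, random_spectrum):
        w, y = random_spectrum.wavenumbers, random_spectrum.intensities
        np.testing.assert_array_equal(_lower_hull_indices(w, y), brute_lower_hull(w, y))

    def test_corrected_nonnegative_and_zero_at_vertices(self, random_spectrum):
        base, corr = rd.rubberband_baseline(random_spectrum)
        assert corr.intensities.min() >= -1e-10
        idx = _lower_hull_indices(random_spectrum.wavenumbers, random_spectrum.intensities)
        np.testing.assert_allclose(corr.intensities[idx], 0.0, atol=1e-10)

    @given(slope=st.floats(-5.0, 5.0), intercept=st.floats(-50.0, 50.0))
    def test_invariant_to_added_linear_trend(self, slope, intercept):
        rng = np.random.default_rng(1)
        w = np.arange(120.0)
        y = rng.normal(10.0, 2.0, w.size)
        _, corr0 = rd.rubberband_baseline(spec(y, w))
        _, corr1 = rd.rubberband_baseline(spec(y + slope * w + intercept, w))
        np.testing.assert_allclose(corr1.intensities, corr0.intensities, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(rd.SpectrumError):
            rd.rubberband_baseline(rd.Spectrum([0.0, 1.0], [0.0, 1.0]))


class TestCrop:
    def test_amide_band_limits(self):
        w = np.arange(400.0, 1801.0)
        out = rd.crop(spec(np.ones(w.size), w), 1598.0, 1688.0)
        assert out.wavenumbers[0] == 1598.0 and out.wavenumbers[-1] == 1688.0
        assert len(out) == 91  # closed interval at 1 cm^-1 spacing

    def test_full_axis_crop_is_identity(self, random_spectrum):
        out = rd.crop(random_spectrum, random_spectrum.wavenumbers[0], random_spectrum.wavenumbers[-1])
        np.testing.assert_array_equal(out.intensities, random_spectrum.intensities)

    def test_two_channel_crop(self):
        w = np.arange(990.0, 1011.0)
        out = rd.crop(spec(w.copy(), w), 1000.0, 1001.0)
        assert len(out) == 2

    def test_empty_crop_rejected(self, random_spectrum):
        with pytest.raises(rd.SpectrumError):
            rd.crop(random_spectrum, 10.0, 11.0)


class TestPipeline:
    def test_rows_processed_independently(self, rng):
        w = 600.0 + np.arange(64.0)
        block = rd.SpectraBlock(w, rng.normal(5.0, 2.0, (3, 64)), ("a", "b", "c"))
        proc, log = rd.apply_pipeline(block, rd.PreprocessConfig.parse("snv"))
        for row in proc.intensities:
            assert abs(row.mean()) < 1e-12
            assert abs(np.std(row, ddof=1) - 1.0) < 1e-12
        assert log[0]["step"] == "snv"

    def test_empty_pipeline_is_identity(self, rng):
        w = 600.0 + np.arange(32.0)
        block = rd.SpectraBlock(w, rng.normal(size=(2, 32)), ("a", "b"))
        proc, log = rd.apply_pipeline(block, rd.PreprocessConfig(()))
        np.testing.assert_array_equal(proc.intensities, block.intensities)
        assert log == []

    def test_composition_matches_manual_sequential_calls(self, rng):
        w = 600.0 + np.arange(128.0)
        block = rd.SpectraBlock(w, rng.normal(10.0, 3.0, (4, 128)), tuple("abcd"))
        cfg = rd.PreprocessConfig.parse("snv,savgol:15:1:1")
        proc, _ = rd.apply_pipeline(block, cfg)
        manual = np.vstack(
            [
                rd.savgol_filter(rd.snv_normalize(s), 15, 1, 1).intensities
                for s in block
            ]
        )
        np.testing.assert_array_equal(proc.intensities, manual)

    def test_axis_preserved_bit_for_bit(self, rng):
        w = 600.0 + np.arange(128.0) * (1.0 + 1e-12)
        block = rd.SpectraBlock(w, rng.normal(10.0, 3.0, (2, 128)), ("a", "b"))
        for steps in ("snv", "savgol:15:1:1", "rubberband"):
            proc, _ = rd.apply_pipeline(block, rd.PreprocessConfig.parse(steps))
            assert proc.wavenumbers.tobytes() == block.wavenumbers.tobytes()

    def test_errors_name_offending_sample(self):
        w = 600.0 + np.arange(16.0)
        m = np.vstack([np.arange(16.0), np.full(16, 3.0)])
        block = rd.SpectraBlock(w, m, ("good", "flatline"))
        with pytest.raises(rd.DegenerateSpectrumError, match="flatline"):
            rd.apply_pipeline(block, rd.PreprocessConfig.parse("snv"))

    def test_parse_round_trip_and_presets(self):
        cfg = rd.PreprocessConfig.parse("snv,savgol:25:2:2,crop:1598:1688,rubberband")
        assert cfg.describe() == "snv,savgol:25:2:2,crop:1598.0:1688.0,rubberband"
        with pytest.raises(rd.SpectrumError):
            rd.PreprocessConfig.parse("savgol:14:2:1")
        assert set(rd.PRESETS) >= {"zeroth", "first_derivative", "second_derivative"}
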
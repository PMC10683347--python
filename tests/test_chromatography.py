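import numpy as np
import pytest

import raman_dbc as rd


class TestOversaturationLoad:
    def test_identity_case(self):
        assert rd.oversaturation_load(4.7, 1.0, 4.7) == pytest.approx(1.0)

    def test_inverted_for_double_manufacturer_capacity(self):
        # loading to twice a 35 mg/mL capacity at C0 = 2, Vc = 4.7 needs 164.5 mL
        v_inject = 2 * 35.0 * 4.7 / 2.0
        assert v_inject == pytest.approx(164.5)
        assert rd.oversaturation_load(v_inject, 2.0, 4.7) == pytest.approx(70.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            v, c, vc = rng.uniform(0.1, 100.0, 3)
            assert rd.oversaturation_load(v, c, vc) == pytest.approx(v * c / vc)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(rd.ChromatographyError):
            rd.oversaturation_load(0.0, 1.0, 1.0)


class TestStandardCurve:
    def test_exact_line_recovered(self):
        masses = np.array([0.005, 0.01, 0.02, 0.03])
        curve = rd.fit_standard_curve(masses, 1000.0 * masses + 5.0)
        assert curve.m == pytest.approx(1000.0)
        assert curve.b == pytest.approx(5.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_within_three_se(self):
        # injection series of a 1.00 mg/mL standard: masses 0.005-0.030 mg
        cfg = rd.SynthConfig(seed=3, std_m=1000.0, std_b=5.0, area_noise_sigma=0.2)
        hits_m, hits_b = 0, 0
        n_rep = 20
        for k in range(n_rep):
            rng = np.random.default_rng(100 + k)
            masses, areas = rd.generate_standard_curve_data(cfg, rng=rng)
            assert masses.min() == pytest.approx(0.005) and masses.max() == pytest.approx(0.030)
            curve = rd.fit_standard_curve(masses, areas)
            x = masses - masses.mean()
            se_m = curve.residual_sd / np.sqrt((x**2).sum())
            se_b = curve.residual_sd * np.sqrt(1 / len(masses) + masses.mean() ** 2 / (x**2).sum())
            hits_m += abs(curve.m - 1000.0) <= 3 * se_m
            hits_b += abs(curve.b - 5.0) <= 3 * se_b
        assert hits_m >= n_rep - 2 and hits_b >= n_rep - 2

    def test_identical_masses_rejected(self):
        with pytest.raises(rd.ChromatographyError):
            rd.fit_standard_curve([0.01, 0.01], [10.0, 12.0])


class TestTiterConversions:
    def test_intercept_area_gives_zero_titer(self):
        curve = rd.StandardCurve(m=1000.0, b=5.0, residual_sd=0.0, n=7)
        assert rd.titer_from_peak_area(curve, 5.0, 0.01) == 0.0

    def test_hand_arithmetic(self):
        curve = rd.StandardCurve(m=1000.0, b=0.0, residual_sd=0.0, n=7)
        assert rd.titer_from_peak_area(curve, 20.0, 0.010) == pytest.approx(2.0)

    def test_round_trip_inversion(self):
        curve = rd.StandardCurve(m=812.0, b=3.3, residual_sd=0.0, n=7)
        titer, iv = 1.7, 0.015
        area = curve.m * titer * iv + curve.b
        assert rd.titer_from_peak_area(curve, area, iv) == pytest.approx(titer, rel=1e-12)

    def test_negative_mass_clips_with_warning(self):
        curve = rd.StandardCurve(m=1000.0, b=5.0, residual_sd=0.0, n=7)
        with pytest.warns(UserWarning, match="clipped"):
            assert rd.titer_from_peak_area(curve, 4.0, 0.01) == 0.0

    def test_beer_lambert(self):
        assert rd.titer_from_absorbance(1.44, 1.44, 1.0) == pytest.approx(1.0)
        assert rd.titer_from_absorbance(0.0, 1.44, 1.0) == 0.0
        for a, e, l in [(0.7, 1.46, 0.2), (2.0, 1.44, 1.0)]:
            assert rd.titer_from_absorbance(a, e, l) == pytest.approx(a / (e * l))
        with pytest.raises(rd.ChromatographyError):
            rd.titer_from_absorbance(1.0, 0.0, 1.0)


class TestBreakthrough:
    def test_flat_zero_and_flat_unity_curves(self):
        table = rd.FractionTable.from_titers(np.zeros(10), c0=2.0)
        assert np.all(rd.build_breakthrough(table).ratios == 0.0)
        table = rd.FractionTable.from_titers(np.full(10, 2.0), c0=2.0)
        assert np.all(rd.build_breakthrough(table).ratios == 1.0)

    def test_midpoint_ratios_match_generator_closed_form(self):
        cfg = rd.SynthConfig(seed=1)
        run = rd.generate_breakthrough_run(cfg)
        curve = rd.build_breakthrough(run.fractions)
        expected = cfg.breakthrough_titer(run.fractions.midpoints) / cfg.c0
        np.testing.assert_allclose(curve.ratios, expected, rtol=1e-12)

    def test_v10_hand_interpolation(self):
        curve = rd.BreakthroughCurve([10.0, 12.0], [0.05, 0.15])
        assert rd.find_v10(curve) == pytest.approx(11.0)

    def test_v10_exact_hit_returns_sampled_point(self):
        curve = rd.BreakthroughCurve([5.0, 10.0, 15.0], [0.0, 0.10, 0.5])
        assert rd.find_v10(curve) == 10.0

    def test_v10_closed_form_of_logistic(self):
        cfg = rd.SynthConfig(seed=2)
        run = rd.generate_breakthrough_run(cfg)
        v10 = rd.find_v10(rd.build_breakthrough(run.fractions))
        assert abs(v10 - (cfg.v_mid_mL - np.log(9.0) / cfg.k_per_mL)) < cfg.fraction_mL

    def test_v10_error_cases(self):
        with pytest.raises(rd.ChromatographyError, match="not saturated"):
            rd.find_v10(rd.BreakthroughCurve([1.0, 2.0], [0.0, 0.05]))
        with pytest.raises(rd.ChromatographyError, match="past breakthrough"):
            rd.find_v10(rd.BreakthroughCurve([1.0, 2.0], [0.5, 0.9]))

    def test_malformed_fraction_tables_rejected(self):
        with pytest.raises(rd.ChromatographyError):
            rd.FractionTable([0.0, 1.0], [2.0, 3.0], [0.0, 0.0], 2.0)  # gap
        with pytest.raises(rd.ChromatographyError):
            rd.FractionTable([0.0, 2.0], [2.0, 4.0], [-0.1, 0.0], 2.0)  # negative titer


class TestDBC:
    def test_zero_when_v10_equals_offset(self):
        res = rd.dbc_10(1.0, rd.ColumnSpec(4.7, 1.0), 2.0)
        assert res.dbc_mg_per_mL == 0.0

    def test_hand_arithmetic(self):
        res = rd.dbc_10(51.0, rd.ColumnSpec(4.7, 1.0), 2.0)
        assert res.dbc_mg_per_mL == pytest.approx(100.0 / 4.7)
        assert res.dbc_mg_per_mL == pytest.approx(21.2766, abs=1e-4)

    def test_v10_below_offset_rejected(self):
        with pytest.raises(rd.ChromatographyError):
            rd.dbc_10(0.5, rd.ColumnSpec(4.7, 1.0), 2.0)

    def test_end_to_end_recovery_on_synthetic_run(self):
        cfg = rd.SynthConfig(seed=11)
        run = rd.generate_breakthrough_run(cfg)
        v10 = rd.find_v10(rd.build_breakthrough(run.fractions))
        res = rd.dbc_10(v10, cfg.column, cfg.c0)
        assert res.dbc_mg_per_mL == pytest.approx(run.truth.dbc_mg_per_mL, rel=0.02)

    def test_refinement_consistency(self):
        # splitting a fraction into two halves with the same titer moves the
        # DBC by less than the interpolation error of one fraction width
        cfg = rd.SynthConfig(seed=4)
        run = rd.generate_breakthrough_run(cfg)
        t = run.fractions.titer
        vs, ve = run.fractions.v_start, run.fractions.v_end
        split_vs, split_ve, split_t = [], [], []
        for a, b, titer in zip(vs, ve, t):
            m = 0.5 * (a + b)
            split_vs += [a, m]
            split_ve += [m, b]
            split_t += [titer, titer]
        fine = rd.FractionTable(split_vs, split_ve, split_t, cfg.c0)
        coarse_dbc = rd.dbc_10(
            rd.find_v10(rd.build_breakthrough(run.fractions)), cfg.column, cfg.c0
        ).dbc_mg_per_mL
        fine_dbc = rd.dbc_10(
            rd.find_v10(rd.build_breakthrough(fine)), cfg.column, cfg.c0
        ).dbc_mg_per_mL
        assert abs(fine_dbc - coarse_dbc) < cfg.fraction_mL * cfg.c0 / cfg.v_c_mL

    def test_dbc_monotone_in_breakthrough_delay(self):
        cfg = rd.SynthConfig(seed=4)
        dbcs = []
        for target in (25.0, 30.0, 35.0, 40.0):
            run = rd.generate_breakthrough_run(cfg.with_target_dbc(target))
            v10 = rd.find_v10(rd.build_breakthrough(run.fractions))
            dbcs.append(rd.dbc_10(v10, cfg.column, cfg.c0).dbc_mg_per_mL)
        assert np.all(np.diff(dbcs) > 0)


class TestUVRoute:
    def test_cross_method_consistency_on_noiseless_trace(self):
        cfg = rd.SynthConfig(seed=6, uv_noise_au=0.0)
        run = rd.generate_breakthrough_run(cfg)
        frac_dbc = rd.dbc_10(
            rd.find_v10(rd.build_breakthrough(run.fractions)), cfg.column, cfg.c0
        ).dbc_mg_per_mL
        uv_dbc = rd.dbc_from_uv_chromatogram(
            run.uv_volumes, run.uv_a280, cfg.column, cfg.c0, cfg.epsilon, cfg.path_cm,
            baseline_until=5.0,
        ).dbc_mg_per_mL
        assert uv_dbc == pytest.approx(frac_dbc, rel=0.01)

    def test_plateau_mode_agrees_with_beer_lambert_mode(self):
        cfg = rd.SynthConfig(seed=6, uv_noise_au=0.0)
        run = rd.generate_breakthrough_run(cfg)
        kwargs = dict(baseline_until=5.0)
        a = rd.dbc_from_uv_chromatogram(
            run.uv_volumes, run.uv_a280, cfg.column, cfg.c0, cfg.epsilon, cfg.path_cm,
            mode="beer_lambert", **kwargs,
        )
        b = rd.dbc_from_uv_chromatogram(
            run.uv_volumes, run.uv_a280, cfg.column, cfg.c0, cfg.epsilon, cfg.path_cm,
            mode="plateau", **kwargs,
        )
        assert b.dbc_mg_per_mL == pytest.approx(a.dbc_mg_per_mL, rel=0.02)

    def test_zero_absorbance_trace_not_saturated(self):
        v = np.arange(0.0, 50.0, 0.5)
        with pytest.raises(rd.ChromatographyError, match="not saturated"):
            rd.dbc_from_uv_chromatogram(
                v, np.zeros_like(v), rd.ColumnSpec(4.7, 1.2), 2.5, 1.44, 0.2,
                baseline_until=5.0,
            )

    def test_dbc_stable_under_uv_noise(self):
        cfg = rd.SynthConfig(seed=0)
        truth = cfg.true_dbc()
        vals = []
        for k in range(20):
            run = rd.generate_breakthrough_run(cfg.replace(seed=200 + k))
            vals.append(
                rd.dbc_from_uv_chromatogram(
                    run.uv_volumes, run.uv_a280, cfg.column, cfg.c0, cfg.epsilon,
                    cfg.path_cm, baseline_until=5.0,
                ).dbc_mg_per_mL
            )
        assert np.all(np.abs(np.array(vals) - truth) / truth < 0.05)
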
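"""Michaelis–Menten, linear low-[S], and depletion estimators; assay helpers."""

import numpy as np
import pytest

from mannomap import (
    ActivityMeasurement,
    DepletionSeries,
    KineticSeries,
    fit_depletion,
    fit_linear_efficiency,
    fit_michaelis_menten,
    initial_rate,
    pahbah_calibrate,
    specific_activity_to_turnover,
)
from mannomap.synthetic_data import NoiseModel, gen_depletion_series, gen_mm_series

S_GRID = np.linspace(0.1, 10.0, 10)


class TestMichaelisMenten:
    def test_recovers_guar_wild_type_efficiency(self):
        """Noise-free rates generated at kcat 636 s⁻¹, K_M 2.2 mg/ml give
        back the catalytic efficiency of 289 ml/(mg·s)."""
        series = gen_mm_series(636.0, 2.2, 4e-9, S_GRID)
        fit = fit_michaelis_menten(series)
        assert round(fit.efficiency) == 289
        assert fit.kcat == pytest.approx(636.0, rel=1e-6)
        assert fit.K_M == pytest.approx(2.2, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("kcat", [50.0, 475.0, 1000.0])
    @pytest.mark.parametrize("km", [0.3, 2.2, 8.0])
    def test_noise_free_recovery_across_grid(self, kcat, km):
        series = gen_mm_series(kcat, km, 4e-9, S_GRID)
        fit = fit_michaelis_menten(series)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.K_M == pytest.approx(km, rel=1e-6)
        assert fit.efficiency == pytest.approx(fit.kcat / fit.K_M, rel=1e-9)

    def test_saturation_diagnostic_flags_low_max_s(self):
        series = gen_mm_series(400.0, 10.0, 18e-9, np.linspace(0.1, 5.0, 8))
        with pytest.warns(UserWarning, match="saturation was not reached"):
            fit = fit_michaelis_menten(series)
        assert fit.warnings

    def test_too_few_concentrations_errors(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_michaelis_menten(KineticSeries([1.0, 1.0, 2.0], [0.1, 0.1, 0.2], 1e-9))

    def test_all_zero_rates_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_michaelis_menten(KineticSeries([1, 2, 3, 4], [0, 0, 0, 0], 1e-9))


class TestLinearEfficiency:
    def test_exact_on_linear_data(self):
        s = np.linspace(0.05, 1.0, 20)
        series = KineticSeries(s, 3.0 * s, enzyme_conc=2.0)
        fit = fit_linear_efficiency(series)
        assert fit.efficiency == pytest.approx(1.5, rel=1e-12)
        assert fit.kcat is None and fit.K_M is None

    def test_low_s_limit_approximates_mm_efficiency(self):
        kcat, km, e = 636.0, 2.2, 4e-9
        s = np.concatenate([np.linspace(km / 200, km / 20, 10), [5 * km]])
        series = gen_mm_series(kcat, km, e, s)
        fit = fit_linear_efficiency(series)
        assert fit.efficiency == pytest.approx(kcat / km, rel=0.05)

    def test_saturating_data_only_errors(self):
        s = np.array([5.0, 6.0, 8.0, 10.0])
        series = gen_mm_series(400.0, 0.5, 1e-9, s)
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_linear_efficiency(series)


class TestDepletion:
    TIMES = np.arange(2.0, 50.0, 5.4) * 60.0  # s

    def test_recovers_wild_type_efficiency_84(self):
        """Noise-free depletion at the reported wild-type efficiency and
        2 nM enzyme gives back 84 s⁻¹·mM⁻¹ using points below 25% conversion."""
        series = gen_depletion_series(84.0, 2e-6, 0.1, self.TIMES)
        fit = fit_depletion(series)
        assert round(fit.efficiency) == 84
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_substrate_gives_zero_efficiency(self):
        series = DepletionSeries(self.TIMES, np.full(len(self.TIMES), 0.1), 0.1, 2e-6)
        assert fit_depletion(series).efficiency == 0.0

    def test_only_points_below_25_percent_conversion_used(self):
        # steep depletion: late points exceed the cutoff but must not bias the fit
        eff = 84.0
        series = gen_depletion_series(eff, 2e-5, 0.1, self.TIMES)
        assert (1 - series.substrate / series.s0).max() > 0.25
        fit = fit_depletion(series)
        assert fit.efficiency == pytest.approx(eff, rel=1e-9)

    def test_all_points_beyond_cutoff_error(self):
        t = np.array([1000.0, 2000.0, 3000.0])
        s = np.array([0.05, 0.02, 0.01])
        with pytest.raises(ValueError, match="conversion"):
            fit_depletion(DepletionSeries(t, s, 0.1, 2e-6))

    def test_nonpositive_substrate_rejected(self):
        with pytest.raises(ValueError):
            DepletionSeries(np.array([1.0, 2.0]), np.array([0.1, 0.0]), 0.1, 2e-6)

    # Accuracy is probed on a dense 1-min grid inside the usable (<25%
    # conversion) window so the Monte-Carlo measures the estimator, not the
    # stochastic inclusion of points straddling the conversion cutoff.
    DENSE_TIMES = np.arange(1.0, 29.0) * 60.0

    def test_two_percent_noise_median_error_below_3_percent(self):
        rng = np.random.default_rng(11)
        errors = []
        for _ in range(200):
            series = gen_depletion_series(
                84.0, 2e-6, 0.1, self.DENSE_TIMES, NoiseModel(0.02), rng
            )
            errors.append(abs(fit_depletion(series).efficiency - 84.0) / 84.0)
        assert np.median(errors) < 0.03

    def test_estimator_bias_below_one_percent(self):
        rng = np.random.default_rng(12)
        estimates = [
            fit_depletion(
                gen_depletion_series(84.0, 2e-6, 0.1, self.DENSE_TIMES, NoiseModel(0.02), rng)
            ).efficiency
            for _ in range(200)
        ]
        assert abs(np.mean(estimates) - 84.0) / 84.0 < 0.01


class TestActivityConversion:
    @pytest.mark.parametrize("u, expected", [(15050, 251), (40, 0.7), (60, 1)])
    def test_reported_rounding(self, u, expected):
        assert specific_activity_to_turnover(u) == expected

    def test_exact_value_and_round_trip(self):
        t = specific_activity_to_turnover(123.4, rounded=False)
        assert t * 60 == pytest.approx(123.4, rel=1e-12)
        ActivityMeasurement(123.4, t)  # invariant holds

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            specific_activity_to_turnover(-1.0)


class TestPahbah:
    def test_exact_linear_recovery(self):
        cal = pahbah_calibrate([(0.0, 0.0), (1.0, 2.0), (2.0, 4.0), (3.0, 6.0)])
        assert cal.apply(4.0) == pytest.approx(2.0, rel=1e-12)

    def test_noise_free_synthetic_curve(self):
        conc = np.linspace(0, 5, 6)
        cal = pahbah_calibrate(list(zip(conc, 1.7 * conc + 0.1)))
        assert cal.apply(1.7 * 2.5 + 0.1) == pytest.approx(2.5, rel=1e-9)

    def test_signal_below_blank_clamped_with_warning(self):
        cal = pahbah_calibrate([(0.0, 1.0), (1.0, 3.0), (2.0, 5.0)])
        with pytest.warns(UserWarning, match="blank"):
            assert cal.apply(0.5) == 0.0

    def test_extrapolation_warns(self):
        cal = pahbah_calibrate([(0.0, 0.0), (1.0, 2.0), (2.0, 4.0)])
        with pytest.warns(UserWarning, match="outside"):
            cal.apply(100.0)

    def test_non_monotone_standards_error(self):
        with pytest.raises(ValueError, match="monotonically"):
            pahbah_calibrate([(0.0, 0.0), (1.0, 3.0), (2.0, 2.0)])


class TestInitialRate:
    def test_exactly_linear_course_uses_all_points(self):
        t = np.linspace(0, 10, 8)
        assert initial_rate(list(zip(t, 2.5 * t))) == pytest.approx(2.5, rel=1e-9)

    def test_plateauing_course_uses_initial_window(self):
        t = np.arange(10.0)
        y = np.where(t <= 4, 3.0 * t, 12.0)  # linear then flat
        rate = initial_rate(list(zip(t, y)))
        assert rate == pytest.approx(3.0, rel=1e-6)

    def test_two_points_error(self):
        with pytest.raises(ValueError):
            initial_rate([(0.0, 0.0), (1.0, 1.0)])

    def test_no_acceptable_window_errors(self):
        rng = np.random.default_rng(0)
        t = np.arange(5.0)
        y = rng.random(5) * 100
        with pytest.raises(ValueError, match="no initial window"):
            initial_rate(list(zip(t, y)), r2_threshold=0.9999)
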
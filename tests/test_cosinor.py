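"""Cosinor design, fitting, polar parameters, significance tests, extrema and
week windowing — checked against closed forms, an independent normal-equations
solver, statsmodels OLS, and Monte Carlo."""

import math

import numpy as np
import pytest

from rhythmlink import (
    HourlySeries,
    RhythmProfile,
    build_design,
    component_parameters,
    curve_extrema,
    fit_cosinor,
    inject_missing,
    rhythm_tests,
    simulate_feature_stream,
    window_fits,
)
from rhythmlink.cosinor import CosinorRegressor, UnderdeterminedDesignError


def series_from(values, start_hour=0, pid="p0", feat="f"):
    values = np.asarray(values, dtype=float)
    return HourlySeries(pid, feat, start_hour + np.arange(len(values)), values)


class TestDesign:
    def test_reference_time_rows(self):
        d = build_design([0.0, 6.0, 1.0, 2.0, 3.0], periods=[24])
        np.testing.assert_allclose(d.matrix[0], [1.0, 1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(d.matrix[1], [1.0, 0.0, 1.0], atol=1e-12)

    def test_three_periods_seven_columns_lcm_24(self):
        d = build_design(np.arange(10.0), periods=[8, 12, 24])
        assert d.matrix.shape[1] == 7
        assert d.fundamental_period == 24.0

    def test_underdetermined_rejected(self):
        with pytest.raises(UnderdeterminedDesignError):
            build_design(np.arange(6.0), periods=[8, 12, 24])


class TestFit:
    def test_noiseless_single_component_exact(self, noiseless_profile):
        s = simulate_feature_stream(noiseless_profile, 72, seed=0)
        fit = fit_cosinor(s, periods=(24,))
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude[24.0] == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase[24.0] == pytest.approx(14.0, abs=1e-9)
        assert fit.percent_rhythm[24.0] == 1.0
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_constant_series_has_no_rhythm(self):
        fit = fit_cosinor(series_from(np.full(48, 5.0)))
        assert fit.mesor == pytest.approx(5.0)
        for period in fit.periods:
            assert fit.amplitude[period] == pytest.approx(0.0, abs=1e-9)
        assert fit.integrated_p == 1.0

    def test_matches_independent_normal_equations(self, rng):
        """Coefficients agree with a from-scratch (X'X)^-1 X'y solve."""
        t = np.arange(200.0)
        y = (
            10
            + 2 * np.cos(2 * np.pi * (t - 14) / 24)
            + 1 * np.cos(2 * np.pi * (t - 3) / 12)
            + rng.normal(0, 1, t.size)
        )
        model = CosinorRegressor(periods=(8, 12, 24)).fit(t, y)
        X = np.column_stack(
            [np.ones_like(t)]
            + [f(2 * np.pi * t / T) for T in (8, 12, 24) for f in (np.cos, np.sin)]
        )
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coef_, expected, atol=1e-8)

    def test_matches_statsmodels_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t = np.arange(168.0)
        y = 5 + np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.5, t.size)
        model = CosinorRegressor(periods=(24,)).fit(t, y)
        X = np.column_stack(
            [np.ones_like(t), np.cos(2 * np.pi * t / 24), np.sin(2 * np.pi * t / 24)]
        )
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(model.coef_, res.params, atol=1e-10)
        np.testing.assert_allclose(model.covariance_, res.cov_params(), atol=1e-10)
        assert model.integrated_p_ == pytest.approx(res.f_pvalue, rel=1e-8)
        assert model.integrated_percent_rhythm_ == pytest.approx(res.rsquared, rel=1e-10)

    def test_missing_values_rejected(self):
        values = np.ones(48)
        values[3] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_cosinor(HourlySeries("p", "f", np.arange(48), values))

    def test_time_shift_equivariance(self, three_component_profile):
        """Shifting the sampling window by k hours shifts every phase
        quantity by k (mod period) and leaves M, A, PR, P unchanged."""
        k = 5
        full = simulate_feature_stream(three_component_profile, 504 + k, seed=0)
        base = HourlySeries("p0", "f", np.arange(504), full.values[:504])
        shifted = HourlySeries("p0", "f", np.arange(504), full.values[k : 504 + k])
        a = fit_cosinor(base)
        b = fit_cosinor(shifted)
        assert b.mesor == pytest.approx(a.mesor, abs=1e-8)
        for T in a.periods:
            assert b.amplitude[T] == pytest.approx(a.amplitude[T], abs=1e-8)
            assert (a.acrophase[T] - b.acrophase[T]) % T == pytest.approx(k % T, abs=1e-6)
            assert b.percent_rhythm[T] == pytest.approx(a.percent_rhythm[T], abs=1e-10)
        assert (a.orthophase - b.orthophase) % a.fundamental_period == pytest.approx(
            k, abs=1 / 30
        )


class TestComponentParameters:
    cov = np.diag([0.01, 0.04, 0.04])

    def test_aligned_component(self):
        amp, phi, *_ = component_parameters(2.0, 0.0, self.cov, 24)
        assert amp == 2.0 and phi == 0.0

    def test_pure_negative_sine_peaks_at_18(self):
        amp, phi, *_ = component_parameters(0.0, -2.0, self.cov, 24)
        assert amp == 2.0
        assert phi == pytest.approx(18.0)

    def test_zero_amplitude_has_undefined_phase_se(self):
        amp, phi, amp_se, phi_se, mesor_se = component_parameters(0.0, 0.0, self.cov, 24)
        assert amp == 0.0 and math.isnan(phi_se)
        assert mesor_se == pytest.approx(0.1)

    def test_delta_method_matches_monte_carlo(self, rng):
        """amp_se/phi_se agree with the SD of the polar transform over
        100,000 Gaussian coefficient draws (within 5%)."""
        beta, gamma, sd = 1.0, 1.0, 0.2
        cov = np.diag([0.01, sd**2, sd**2])
        _, _, amp_se, phi_se, _ = component_parameters(beta, gamma, cov, 24)
        draws_b = rng.normal(beta, sd, 100_000)
        draws_g = rng.normal(gamma, sd, 100_000)
        amp_mc = np.hypot(draws_b, draws_g).std()
        phi_mc = (24 / (2 * np.pi)) * np.arctan2(draws_g, draws_b).std()
        assert amp_se == pytest.approx(amp_mc, rel=0.05)
        assert phi_se == pytest.approx(phi_mc, rel=0.05)

    def test_asymmetric_covariance_rejected(self):
        bad = np.array([[1, 0.5, 0], [0, 1, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            component_parameters(1.0, 1.0, bad, 24)


class TestRhythmTests:
    def test_pure_24h_cosine_concentrates_in_its_period(self, noiseless_stream):
        pr, p, ipr, ip = rhythm_tests(noiseless_stream, periods=(8, 12, 24))
        assert pr[24.0] == pytest.approx(1.0, abs=1e-12)
        assert p[24.0] == 0.0
        assert pr[8.0] == pytest.approx(0.0, abs=1e-12)
        assert ipr == 1.0 and ip == 0.0

    def test_nestedness_on_noisy_streams(self, rng):
        for seed in range(25):
            prof = RhythmProfile(
                mesor=float(rng.uniform(5, 15)),
                amp_by_period={8: rng.uniform(0, 1), 12: rng.uniform(0, 1),
                               24: rng.uniform(0, 3)},
                acro_by_period={8: rng.uniform(0, 8), 12: rng.uniform(0, 12),
                                24: rng.uniform(0, 24)},
                noise_sd=float(rng.uniform(0.5, 2)),
            )
            s = simulate_feature_stream(prof, 336, seed=seed)
            pr, _, ipr, _ = rhythm_tests(s)
            assert ipr >= max(pr.values()) - 1e-12

    def test_type_i_error_near_alpha(self, rng):
        """Zero-amplitude test on white noise rejects at ~5% (quick check at
        1,000 replicates; the full 10,000-replicate calibration runs in the
        acceptance suite)."""
        t = np.arange(168.0)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            model = CosinorRegressor(periods=(24,)).fit(t, rng.standard_normal(168))
            rejections += model.p_value_[24.0] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestExtrema:
    def test_single_component_geometry(self):
        # M=0, A=2 at phase 14 h
        beta = 2 * np.cos(2 * np.pi * 14 / 24)
        gamma = 2 * np.sin(2 * np.pi * 14 / 24)
        mag, ortho, bathy = curve_extrema([0.0, beta, gamma], periods=[24])
        assert mag == pytest.approx(2.0, abs=1e-6)
        assert ortho == pytest.approx(14.0, abs=1 / 60)
        assert bathy == pytest.approx(2.0, abs=1 / 60)

    def test_constant_curve_ties_break_earliest(self):
        mag, ortho, bathy = curve_extrema([5.0, 0.0, 0.0], periods=[24])
        assert mag == 0.0 and ortho == 0.0 and bathy == 0.0

    def test_two_component_matches_fine_grid(self):
        """1-minute grid extrema agree with a 1-second brute-force scan
        within one minute."""
        coef_sorted = [0.0]  # order matches sorted periods: 12 h then 24 h
        for A, phi, T in ((1.0, 3.0, 12.0), (2.0, 14.0, 24.0)):
            w = 2 * np.pi * phi / T
            coef_sorted += [A * np.cos(w), A * np.sin(w)]
        t_fine = np.arange(0, 24, 1 / 3600)
        curve = (
            coef_sorted[1] * np.cos(2 * np.pi * t_fine / 12)
            + coef_sorted[2] * np.sin(2 * np.pi * t_fine / 12)
            + coef_sorted[3] * np.cos(2 * np.pi * t_fine / 24)
            + coef_sorted[4] * np.sin(2 * np.pi * t_fine / 24)
        )
        mag2, ortho2, bathy2 = curve_extrema(coef_sorted, periods=[12, 24])
        assert mag2 == pytest.approx((curve.max() - curve.min()) / 2, abs=1e-4)
        assert ortho2 == pytest.approx(t_fine[np.argmax(curve)], abs=1 / 60)
        assert bathy2 == pytest.approx(t_fine[np.argmin(curve)], abs=1 / 60)


class TestWindowFits:
    def _stream(self, n_weeks=16):
        prof = RhythmProfile(
            mesor=10, amp_by_period={24: 2}, acro_by_period={24: 14}, noise_sd=0.5
        )
        return simulate_feature_stream(prof, n_weeks * 168, seed=0)

    def test_window_extents(self):
        fits, log = window_fits([self._stream()], survey_weeks=(1, 6, 15), periods=(24,))
        spans = {
            row.week: (row.window_start_hour, row.window_stop_hour)
            for row in log.itertuples()
        }
        assert spans[6] == (4 * 168, 7 * 168)  # weeks 5-7
        assert spans[1] == (0, 2 * 168)  # truncated at study start
        assert spans[15] == (13 * 168, 16 * 168)  # weeks 14-16
        assert {f.week for f in fits} == {1, 6, 15}
        assert all(f.n_obs in (336, 504) for f in fits)

    def test_discard_rule_applies_per_window(self):
        s = self._stream()
        # blank out most of weeks 5-7 so only the week-6 window is discarded
        values = s.values.copy()
        mask = np.zeros_like(s.missing_mask)
        mask[4 * 168 : 6 * 168] = True
        values[mask] = np.nan
        broken = HourlySeries("p0", "f", s.hours, values, mask)
        fits, log = window_fits([broken], survey_weeks=(1, 6, 15), periods=(24,))
        decisions = dict(zip(log["week"], log["decision"]))
        assert decisions[6] == "discarded"
        assert decisions[1] == decisions[15] == "fitted"
        assert {f.week for f in fits} == {1, 15}

    def test_acrophase_referenced_to_window_start(self):
        """A window starting mid-study still reports acrophase from its own
        starting midnight, so the 14-h peak is recovered in every window."""
        fits, _ = window_fits([self._stream()], survey_weeks=(6,), periods=(24,))
        assert fits[0].acrophase[24.0] == pytest.approx(14.0, abs=0.2)
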
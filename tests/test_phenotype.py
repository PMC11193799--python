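"""Nap scoring, circadian alignment, interpolation and curve fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from circanap.melatonin import PhaseEstimate, SBCFParams
from circanap.phenotype import (
    CIRCADIAN_GRID,
    CircadianSeries,
    NapMetrics,
    align_to_dlmon,
    baseline_association,
    circadian_curve,
    fit_circadian_model,
    interpolate_series,
    score_window,
    session_contrasts,
)
from circanap.simulate import Hypnogram


def make_phase(dlmon: float, converged: bool = True) -> PhaseEstimate:
    p = SBCFParams(2.0, 10.0, dlmon + 120.0, 180.0, 240.0, 2.0)
    return PhaseEstimate(dlmon, dlmon + 400.0, p, 0.0, converged)


def make_series(values) -> CircadianSeries:
    return CircadianSeries(CIRCADIAN_GRID.copy(), np.asarray(values, float),
                           "rem_pct", np.zeros(10, bool))


class TestScoreWindow:
    def test_forced_arithmetic(self):
        stages = np.array(["W"] * 40 + ["N2"] * 80 + ["REM"] * 40)
        hyp = Hypnogram(stages, 30.0, "nap_00")
        m = score_window(hyp, 80.0)
        assert m.se == pytest.approx(0.75)
        assert m.rem_pct == pytest.approx(100.0 / 3.0)
        assert m.tst_min == pytest.approx(60.0)

    def test_all_wake_undefined_rem(self):
        hyp = Hypnogram(np.array(["W"] * 160), 30.0, "nap_03")
        m = score_window(hyp, 80.0)
        assert m.se == 0.0
        assert not m.rem_defined

    def test_coverage_mismatch_rejected(self):
        hyp = Hypnogram(np.array(["W"] * 100), 30.0, "nap_00")
        with pytest.raises(ValueError):
            score_window(hyp, 80.0)

    @given(st.lists(st.sampled_from(["W", "N1", "N2", "N3", "REM"]),
                    min_size=160, max_size=160))
    def test_counting_oracle(self, stages):
        hyp = Hypnogram(np.array(stages), 30.0, "nap_00")
        m = score_window(hyp, 80.0)
        # brute-force epoch counting loop
        n_sleep = n_rem = 0
        for s in stages:
            if s != "W":
                n_sleep += 1
            if s == "REM":
                n_rem += 1
        assert m.se == pytest.approx(n_sleep * 0.5 / 80.0)
        if n_sleep:
            assert m.rem_pct == pytest.approx(100.0 * n_rem / n_sleep)
        else:
            assert not m.rem_defined


class TestAlignToDLMOn:
    def test_midpoint_at_dlmon_maps_to_zero(self):
        m = NapMetrics(0, 840.0, 0.5, 20.0, 40.0)
        pts = align_to_dlmon([m], make_phase(840.0))
        assert pts == [(0.0, 20.0)]

    def test_four_hours_after(self):
        m = NapMetrics(0, 840.0 + 240.0, 0.5, 20.0, 40.0)
        pts = align_to_dlmon([m], make_phase(840.0))
        assert pts[0][0] == pytest.approx(4.0)

    def test_default_schedule_arithmetic(self, default_schedule):
        """Nap circadian times agree with direct schedule arithmetic."""
        dlmon = 840.0  # 2 h before habitual sleep time
        metrics = [
            NapMetrics(i, w.midpoint_min, 0.5, 20.0, 40.0)
            for i, w in enumerate(default_schedule.naps)
        ]
        pts = align_to_dlmon(metrics, make_phase(dlmon))
        expected = [(130.0 + 40.0 + 240.0 * i - 840.0) / 60.0 for i in range(10)]
        assert np.allclose([p[0] for p in pts], expected)

    def test_unconverged_phase_rejected(self):
        m = NapMetrics(0, 840.0, 0.5, 20.0, 40.0)
        with pytest.raises(ValueError):
            align_to_dlmon([m], make_phase(840.0, converged=False))

    def test_missing_rem_dropped(self):
        ms = [NapMetrics(0, 840.0, 0.0, np.nan, 0.0),
              NapMetrics(1, 1080.0, 0.5, 25.0, 40.0)]
        pts = align_to_dlmon(ms, make_phase(840.0))
        assert len(pts) == 1


class TestInterpolateSeries:
    def test_identity_at_grid_times(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 40, CIRCADIAN_GRID.size)
        pts = list(zip(CIRCADIAN_GRID, vals))
        series = interpolate_series(pts)
        assert np.allclose(series.values, vals)
        assert not series.clamped.any()

    def test_line_reproduced_exactly(self):
        t = np.array([-12.5, -7.5, -3.0, 1.0, 5.0, 9.0, 13.0, 17.0, 21.0, 24.5])
        pts = list(zip(t, 3.0 + 0.7 * t))
        series = interpolate_series(pts)
        assert np.allclose(series.values, 3.0 + 0.7 * CIRCADIAN_GRID)

    def test_grid_is_the_ten_theoretical_times(self):
        assert np.array_equal(
            CIRCADIAN_GRID,
            np.array([-12, -8, -4, 0, 4, 8, 12, 16, 20, 24], float),
        )

    def test_out_of_span_points_clamped(self):
        t = np.linspace(-10.0, 22.0, 8)
        series = interpolate_series(list(zip(t, np.sin(t))))
        assert series.clamped[0] and series.clamped[-1]
        assert series.values[0] == pytest.approx(np.sin(-10.0), abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            interpolate_series([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])

    def test_duplicate_times_rejected(self):
        pts = [(0.0, 1.0), (0.0, 2.0), (4.0, 3.0), (8.0, 1.0), (12.0, 2.0)]
        with pytest.raises(ValueError):
            interpolate_series(pts)

    def test_interpolation_error_on_generating_model(self, default_schedule):
        """Spline through noiseless nap values errs < 0.5 REM% on the grid."""
        dlmon = 840.0
        t_nap = np.array([(w.midpoint_min - dlmon) / 60.0
                          for w in default_schedule.naps])
        f = lambda t: circadian_curve(t, 10.0, 0.2, 15.0, 8.0, 3.0)
        series = interpolate_series(list(zip(t_nap, f(t_nap))))
        inside = ~series.clamped
        assert np.max(np.abs(series.values[inside] - f(CIRCADIAN_GRID[inside]))) < 0.5


class TestFitCircadianModel:
    TRUTH = (10.0, 0.2, 15.0, 8.0, 3.0)

    def test_noiseless_recovery(self):
        y = circadian_curve(CIRCADIAN_GRID, *self.TRUTH)
        fit = fit_circadian_model(make_series(y))
        assert fit.converged
        for est, true in zip((fit.a, fit.b, fit.h, fit.mu, fit.sigma), self.TRUTH):
            assert est == pytest.approx(true, rel=1e-3)
        assert fit.t_min == pytest.approx(-1.0, abs=1e-3)

    def test_flat_series(self):
        fit = fit_circadian_model(make_series(np.full(10, 22.0)))
        assert fit.h == pytest.approx(0.0, abs=1e-6)
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(22.0)

    def test_linearity_of_least_squares(self):
        y = circadian_curve(CIRCADIAN_GRID, *self.TRUTH)
        base = fit_circadian_model(make_series(y))
        scaled = fit_circadian_model(make_series(2.5 * y))
        assert scaled.a == pytest.approx(2.5 * base.a, rel=1e-3)
        assert scaled.b == pytest.approx(2.5 * base.b, rel=1e-3)
        assert scaled.h == pytest.approx(2.5 * base.h, rel=1e-3)
        shifted = fit_circadian_model(make_series(y + 7.0))
        assert shifted.a == pytest.approx(base.a + 7.0, rel=1e-3)
        assert shifted.h == pytest.approx(base.h, rel=1e-3)

    def test_constraint_activity_on_boundary(self):
        """A series whose free trough is late gets pinned to the window edge."""
        y = circadian_curve(CIRCADIAN_GRID, 10.0, 0.2, 15.0, 13.0, 3.0)
        fit = fit_circadian_model(make_series(y))  # free t_min would be +4
        assert abs(fit.t_min) == pytest.approx(2.0, abs=1e-6)

    def test_trough_always_inside_window(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            y = circadian_curve(CIRCADIAN_GRID, *self.TRUTH) + rng.normal(0, 8, 10)
            fit = fit_circadian_model(make_series(y))
            assert abs(fit.t_min) <= 2.0 + 1e-9
            assert fit.t_min == pytest.approx(fit.mu - 3 * fit.sigma, abs=1e-9)

    def test_literal_convolution_is_degenerate(self):
        """Convolving a line with a unit-mass Gaussian returns the line.

        Documents why the model is additive: under a literal
        convolution reading there is no Gaussian height to extract.
        """
        a, b, sigma = 4.0, 0.7, 3.0
        gauss = lambda u: np.exp(-u**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        for t in (-5.0, 0.0, 7.0):
            val, _ = quad(lambda u: (a + b * (t - u)) * gauss(u), -40, 40)
            assert val == pytest.approx(a + b * t, abs=1e-8)

    def test_recovery_degrades_with_noise(self):
        rng = np.random.default_rng(9)
        rmse = []
        for sd in (1.0, 4.0, 10.0):
            errs = []
            for _ in range(60):
                y = circadian_curve(CIRCADIAN_GRID, *self.TRUTH) + rng.normal(0, sd, 10)
                fit = fit_circadian_model(make_series(y))
                errs.append((fit.h - self.TRUTH[2]) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] < rmse[1] < rmse[2]


class TestSessionContrasts:
    def test_identical_day_and_night_gives_zero(self):
        vals = np.tile(np.linspace(10, 20, 10), (5, 1))
        vals += np.arange(5)[:, None]  # subject offsets, zero paired variance
        out = session_contrasts(vals)
        # differences are identical across subjects -> sd 0 -> effect 0
        assert np.allclose(out["effect"], 0.0)

    def test_planted_difference_standardized(self):
        rng = np.random.default_rng(1)
        n, d, s = 4000, 5.0, 2.0
        vals = np.zeros((n, 10))
        vals[:, :] = 30.0
        vals += rng.normal(0, s, size=(n, 10))
        day_cols = [j for j, g in enumerate(CIRCADIAN_GRID) if g not in (4.0, 8.0)]
        vals[:, day_cols] -= d
        out = session_contrasts(vals)
        # paired diff = -d + noise with sd sqrt(s^2 + s^2/2)
        expected = -d / np.sqrt(s**2 + s**2 / 2)
        assert np.allclose(out["effect"], expected, atol=0.1)

    def test_night_peak_sign_pattern(self):
        """Cohort with a night REM peak: late-day contrasts negative."""
        rng = np.random.default_rng(5)
        vals = circadian_curve(CIRCADIAN_GRID, 10.0, 0.2, 15.0, 8.0, 3.0)
        vals = vals + rng.normal(0, 3, size=(60, 10))
        out = session_contrasts(vals)
        late_day = out.loc[out["grid_h"].isin([-4.0, 0.0, 20.0, 24.0]), "effect"]
        assert (late_day < 0).all()

    def test_subject_missing_night_excluded(self):
        vals = np.full((3, 10), 20.0)
        vals[0, 5] = np.nan  # grid +8 missing
        out = session_contrasts(vals)
        assert out.attrs["n_excluded"] == 1
        assert (out["n"] == 2).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            session_contrasts(np.full((1, 10), 20.0))


class TestBaselineAssociation:
    def test_exact_linear_dependence(self, rng):
        n = 30
        base = rng.uniform(10, 30, n)
        out = baseline_association(2.0 * base, base, rng.normal(size=n),
                                   rng.integers(0, 2, n), rng.normal(size=n))
        assert out["coefficient"] == pytest.approx(2.0, abs=1e-8)
        assert out["t"] > 1e5

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        n = 10
        base = rng.uniform(10, 30, n)
        age = rng.uniform(60, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        se = rng.uniform(70, 95, n)
        y = 5 + 0.8 * base + rng.normal(0, 2, n)
        out = baseline_association(y, base, age, sex, se)
        X = np.column_stack([np.ones(n), base, age, sex, se])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 5)
        se_b = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert out["coefficient"] == pytest.approx(beta[1], abs=1e-10)
        assert out["t"] == pytest.approx(beta[1] / se_b, abs=1e-8)
        assert out["df"] == 5

    def test_type_i_error_calibration(self):
        """Planted null: |t| > t_crit(0.05) in about 5% of replicates."""
        from scipy import stats

        rng = np.random.default_rng(7)
        n, reps = 86, 500
        t_crit = stats.t.ppf(0.975, n - 5)
        hits = 0
        for _ in range(reps):
            base = rng.uniform(10, 30, n)
            age = rng.uniform(60, 80, n)
            sex = rng.integers(0, 2, n)
            se = rng.uniform(70, 95, n)
            y = rng.normal(size=n)
            out = baseline_association(y, base, age, sex, se)
            hits += abs(out["t"]) > t_crit
        rate = hits / reps
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_collinear_design_named(self, rng):
        n = 20
        base = rng.uniform(10, 30, n)
        with pytest.raises(ValueError, match="collinear"):
            baseline_association(rng.normal(size=n), base, base,
                                 rng.integers(0, 2, n), rng.normal(size=n))
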
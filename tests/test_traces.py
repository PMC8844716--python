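"""Trace pipeline: imputation, filtering, spline, detrend, period, embedding,
classification and population summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tetosc as T


def make_trace(values, dt=2.0, cell_id="c"):
    values = np.asarray(values, dtype=float)
    return T.FluorescenceTrace(cell_id, dt * np.arange(len(values)), values)


class TestImputation:
    def test_symmetric_neighbour_mean(self):
        tr = make_trace([1, 2, 3, np.nan, 5, 6, 7])
        out = T.impute_missing(tr)
        assert out.intensities[3] == pytest.approx(4.0)
        assert not out.missing.any()

    def test_identity_without_missing(self):
        tr = make_trace([1.0, 2.0, 3.0, 4.0])
        assert T.impute_missing(tr) is tr

    def test_constant_series(self):
        tr = make_trace([10, 10, 10, np.nan, 10, 10, 10])
        assert T.impute_missing(tr).intensities[3] == pytest.approx(10.0)

    def test_fewer_than_three_neighbours_uses_what_exists(self):
        tr = make_trace([np.nan, 2, 4, 8, 16])
        # isolated leading gap: mean of the (up to 3) following observations
        assert T.impute_missing(tr).intensities[0] == pytest.approx((2 + 4 + 8) / 3)

    def test_run_of_missing_is_linearly_interpolated(self):
        tr = make_trace([0, 2, np.nan, np.nan, 8, 10])
        out = T.impute_missing(tr, max_missing_fraction=0.5)
        assert out.intensities[2] == pytest.approx(4.0)
        assert out.intensities[3] == pytest.approx(6.0)

    def test_too_many_missing_rejected(self):
        vals = np.arange(10.0)
        vals[:3] = np.nan
        with pytest.raises(ValueError):
            T.impute_missing(make_trace(vals))


class TestMovingAverage:
    def test_constant_is_fixed_point(self):
        x = np.full(30, 3.5)
        for n in (0, 1, 5, 8):
            assert np.allclose(T.moving_average(x, n), 3.5)

    def test_zero_window_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(T.moving_average(x, 0), x)

    def test_truncated_boundary_means(self):
        y = T.moving_average(np.arange(1.0, 11.0), 2)
        assert y[0] == pytest.approx(2.0)    # mean of 1,2,3
        assert y[2] == pytest.approx(3.0)    # mean of 1..5
        assert y[9] == pytest.approx(9.0)    # mean of 8,9,10

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            T.moving_average([], 3)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10), st.integers(1, 40), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, n, length, seed):
        x = np.random.default_rng(seed).normal(size=length)
        expected = np.array([
            np.mean(x[max(0, k - n): min(length, k + n + 1)])
            for k in range(length)
        ])
        assert np.allclose(T.moving_average(x, n), expected)

    def test_output_within_input_range(self):
        x = np.random.default_rng(3).normal(size=50)
        y = T.moving_average(x, 8)
        assert y.min() >= x.min() - 1e-12 and y.max() <= x.max() + 1e-12


class TestSpline:
    def test_interpolates_knots_exactly(self):
        t = np.arange(10.0)
        y = np.random.default_rng(1).normal(size=10)
        sp = T.fit_spline(t, y)
        assert np.allclose(T.eval_spline(sp, t), y, atol=1e-12)

    def test_reproduces_cubic_polynomial(self):
        t = np.linspace(0, 5, 8)
        poly = lambda x: 2 * x**3 - x**2 + 3 * x - 7
        sp = T.fit_spline(t, poly(t))
        q = np.linspace(0.1, 4.9, 50)
        assert np.allclose(T.eval_spline(sp, q), poly(q), rtol=1e-9)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            T.fit_spline([0, 1, 1, 2, 3], [0, 1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            T.fit_spline([0, 1, 2], [1, 2, 3])

    def test_five_point_coefficients_match_tridiagonal_solve(self):
        # independent oracle: solve the not-a-knot second-derivative system
        # directly for 5 equally spaced points and compare mid-interval values
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        # natural cubic spline equations replaced by not-a-knot: enforce
        # third-derivative continuity at the first and last interior knots.
        # Unknowns: second derivatives M0..M4 (h = 1).
        A = np.zeros((5, 5))
        b = np.zeros(5)
        for i in (1, 2, 3):
            A[i, i - 1: i + 2] = [1, 4, 1]
            b[i] = 6 * (y[i - 1] - 2 * y[i] + y[i + 1])
        A[0, :3] = [1, -2, 1]     # M0 - 2M1 + M2 = 0 (not-a-knot, left)
        A[4, 2:] = [1, -2, 1]     # M2 - 2M3 + M4 = 0 (right)
        M = np.linalg.solve(A, b)
        sp = T.fit_spline(t, y)
        for i in range(4):
            tm = t[i] + 0.5
            s_oracle = (M[i] / 6 * (t[i + 1] - tm) ** 3
                        + M[i + 1] / 6 * (tm - t[i]) ** 3
                        + (y[i] - M[i] / 6) * (t[i + 1] - tm)
                        + (y[i + 1] - M[i + 1] / 6) * (tm - t[i]))
            assert T.eval_spline(sp, tm) == pytest.approx(s_oracle, abs=1e-10)

    def test_fourth_order_convergence_on_sine(self):
        errs = []
        for n in (16, 32, 64):
            t = np.linspace(0, 2 * np.pi, n + 1)
            sp = T.fit_spline(t, np.sin(t))
            q = np.linspace(0, 2 * np.pi, 1000)
            errs.append(np.max(np.abs(T.eval_spline(sp, q) - np.sin(q))))
        assert errs[0] / errs[1] >= 8
        assert errs[1] / errs[2] >= 8


class TestTrendAndDetrend:
    def test_exact_line(self):
        t = np.arange(10.0)
        m, c = T.fit_linear_trend(t, 2 * t + 1)
        assert (m, c) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_constant_series(self):
        m, c = T.fit_linear_trend(np.arange(5.0), np.full(5, 3.0))
        assert m == pytest.approx(0.0, abs=1e-12) and c == pytest.approx(3.0)

    def test_matches_normal_equations(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        y = np.array([1.0, 2.0, 2.5, 6.0])
        X = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        m, c = T.fit_linear_trend(t, y)
        assert np.allclose([m, c], beta)

    def test_identical_times_rejected(self):
        with pytest.raises(ValueError):
            T.fit_linear_trend([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_pure_line_detrends_to_zero(self):
        t = np.arange(20.0)
        assert np.allclose(T.detrend(5 * t - 3, t), 0, atol=1e-9)

    def test_recovers_projected_oscillation(self):
        # oracle: residual of least-squares projection onto span{1, t}
        t = 2.0 * np.arange(60)
        y = np.sin(2 * np.pi * t / 50) * 20 + 0.3 * t + 40
        X = np.column_stack([np.ones_like(t), t])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(T.detrend(y, t), resid, atol=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_mean_zero_slope_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        t = 2.0 * np.arange(40)
        y = rng.normal(50, 20, size=40)
        d = T.detrend(y, t)
        scale = max(np.abs(y).max(), 1.0)
        assert abs(d.mean()) < 1e-9 * scale
        m, _ = T.fit_linear_trend(t, d)
        assert abs(m) < 1e-9 * scale
        assert np.allclose(T.detrend(d, t), d, atol=1e-9 * scale)


class TestPeriodEstimation:
    def test_noiseless_sine_recovered_within_one_sample(self):
        t = 2.0 * np.arange(60)
        x = np.sin(2 * np.pi * t / 40)
        assert T.estimate_period(t, T.detrend(x, t)) == pytest.approx(40, abs=2)

    def test_constant_series_has_no_period(self):
        t = 2.0 * np.arange(60)
        assert T.estimate_period(t, np.zeros(60)) is None

    def test_white_noise_has_no_period(self):
        t = 2.0 * np.arange(60)
        x = np.random.default_rng(0).normal(size=60)
        # featureless noise must not produce a confident estimate
        p = T.estimate_period(t, T.detrend(x, t))
        assert p is None or not (48 <= p <= 52)

    def test_trended_growing_sine_after_detrend(self):
        t = 2.0 * np.arange(60)
        y = (20 + 0.1 * t) * np.sin(2 * np.pi * t / 50) + 0.2 * t + 100
        assert T.estimate_period(t, T.detrend(y, t)) == pytest.approx(50, abs=2)


class TestEmbedding:
    def test_pair_count(self):
        pairs = T.embed_phase_space(np.arange(60.0), 6)
        assert pairs.shape == (54, 2)
        assert np.array_equal(pairs[:, 0], np.arange(54.0))
        assert np.array_equal(pairs[:, 1], np.arange(6.0, 60.0))

    def test_full_period_delay_lies_on_diagonal(self):
        t = 2.0 * np.arange(60)
        x = np.sin(2 * np.pi * t / 40)   # 40 min = 20 samples
        pairs = T.embed_phase_space(x, 20)
        assert np.max(np.abs(pairs[:, 1] - pairs[:, 0])) < 1e-9

    def test_quarter_period_delay_decorrelates(self):
        t = 2.0 * np.arange(60)
        x = np.sin(2 * np.pi * t / 48)   # quarter period = 6 samples
        pairs = T.embed_phase_space(x, 6)
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert abs(r) < 0.1

    @pytest.mark.parametrize("k", [0, -1, 60, 61])
    def test_invalid_delay_rejected(self, k):
        with pytest.raises(ValueError):
            T.embed_phase_space(np.arange(60.0), k)


class TestClassification:
    def test_all_zero_is_absent(self):
        assert T.classify_trace(make_trace(np.zeros(60))) == "absent"

    def test_linear_decreasing_with_signal(self):
        t = 2.0 * np.arange(60)
        assert T.classify_trace(make_trace(100 - 0.5 * t)) == "decreasing"

    def test_flat_signal_is_constant(self):
        assert T.classify_trace(make_trace(np.full(60, 80.0))) == "constant"

    def test_planted_oscillation_detected(self):
        tr = T.generate_trace(T.TraceSpec("oscillating", noise_sd=0.0, seed=1))
        assert T.classify_trace(tr) == "oscillating"


class TestPopulationSummary:
    def test_published_field_of_view_percentages(self):
        cats = (["absent"] * 40 + ["decreasing"] * 37 + ["constant"] * 3
                + ["oscillating"] * 8)
        s = T.summarize_population(cats)
        assert s.total == 88
        assert s.percentages == {"absent": 45.5, "decreasing": 42.0,
                                 "constant": 3.4, "oscillating": 9.1}

    def test_single_cell(self):
        s = T.summarize_population(["oscillating"])
        assert s.percentages["oscillating"] == 100.0

    def test_equal_split(self):
        s = T.summarize_population(list(T.traces.CATEGORIES))
        assert all(v == 25.0 for v in s.percentages.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            T.summarize_population([])


class TestFullPipeline:
    def test_pipeline_invariants_on_arbitrary_trace(self):
        tr = T.generate_trace(T.TraceSpec("oscillating", noise_sd=5.0, seed=12))
        res = T.analyze_trace(tr)
        scale = max(np.abs(res.filtered).max(), 1.0)
        assert abs(res.detrended.mean()) < 1e-9 * scale
        m, _ = T.fit_linear_trend(tr.times, res.detrended)
        assert abs(m) < 1e-9 * scale
        assert res.phase_pairs.shape == (60 - res.delay_k, 2)

    def test_pipeline_handles_missing_frame(self):
        tr = T.plant_missing(
            T.generate_trace(T.TraceSpec("oscillating", noise_sd=3.0, seed=4)), 21)
        res = T.analyze_trace(tr)
        assert not np.isnan(res.imputed).any()
        assert res.category == "oscillating"

    def test_period_recovery_rate_on_noisy_population(self):
        # 100 planted oscillators, period 50 min, SNR >= 3 (sd 5 on amp 20):
        # at least 90% recovered within +/- 4 min
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            spec = T.TraceSpec("oscillating", noise_sd=5.0, seed=seed,
                               phase=float(rng.uniform(0, 2 * np.pi)))
            p = T.analyze_trace(T.generate_trace(spec)).period
            if p is not None and abs(p - 50) <= 4:
                hits += 1
        assert hits >= 90
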
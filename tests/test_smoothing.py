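"""Kernel densities, knot placement, penalized fits, GCV, and evaluation."""

import numpy as np
import pytest

import movefda as m
from movefda.exceptions import (DegenerateKnotsError, DomainError,
                                ParameterError)
from movefda.smoothing import _gcv_from_parts


class TestTimeDensity:
    def test_single_kernel_peak_value(self):
        d = m.TimeDensity(np.array([0.0]), 1.0)
        assert d(0.0)[0] == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_normalization(self, rng):
        for h in (0.1, 1.0, 5.0):
            d = m.TimeDensity(rng.uniform(0, 50, 200), h)
            t, v = d.grid(4001)
            assert np.trapezoid(v, t) == pytest.approx(1.0, abs=1e-3)

    def test_dense_cluster_beats_sparse(self, rng):
        times = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(9, 10, 10)])
        d = m.estimate_time_density(times, bandwidth=0.3)
        assert d(0.5)[0] > d(9.5)[0]

    def test_statsmodels_cross_check(self, rng):
        # independent KDE implementation agrees pointwise
        from statsmodels.nonparametric.kde import KDEUnivariate
        x = rng.normal(5, 2, 300)
        h = 0.7
        ours = m.TimeDensity(x, h)
        ref = KDEUnivariate(x)
        ref.fit(kernel="gau", bw=h, fft=False)
        grid = np.linspace(0, 10, 21)
        np.testing.assert_allclose(ours(grid), ref.evaluate(grid),
                                   rtol=1e-6, atol=1e-9)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ParameterError):
            m.TimeDensity(np.array([0.0, 1.0]), 0.0)


class TestSelectKnots:
    def test_zero_quantile_retains_all(self):
        times = np.linspace(0, 10, 50)
        d = m.estimate_time_density(times)
        kv = m.select_knots(d, times, quantile=0.0, min_spacing_days=0.0)
        assert len(kv.interior) == 48  # all times strictly inside the domain

    def test_gap_produces_no_interior_knots_in_gap(self, rng):
        times = np.sort(np.concatenate([rng.uniform(0, 10, 120),
                                        rng.uniform(50, 60, 120)]))
        d = m.estimate_time_density(times, bandwidth=1.0)
        kv = m.select_knots(d, times, quantile=0.2)
        assert not np.any((kv.interior > 11) & (kv.interior < 49))

    def test_extreme_quantile_keeps_few_or_raises(self):
        times = np.linspace(0, 10, 200)
        d = m.estimate_time_density(times)
        try:
            kv = m.select_knots(d, times, quantile=0.99,
                                min_spacing_days=0.0)
            assert len(kv.interior) <= 2  # <= 1% of 200
        except DegenerateKnotsError:
            pass


class TestFitPenalized:
    def test_interpolation_limit(self, rng):
        t = np.unique(np.sort(rng.uniform(0, 10, 60)))
        lat = 0.1 * np.sin(t) + 0.002 * rng.standard_normal(len(t))
        track = m.Track("x", t, lat, lat)
        kv = m.KnotVector(t[1:-1], (t[0], t[-1]))
        model = m.fit_penalized(track, kv, 0.0, 0.0)
        _, fitted = model.positions(t)
        assert np.abs(fitted - lat).max() <= 1e-6

    def test_huge_penalty_matches_ols_line(self, rng):
        t = np.unique(np.sort(rng.uniform(0, 10, 80)))
        y = 0.5 + 0.3 * t + 0.01 * rng.standard_normal(len(t))
        track = m.Track("x", t, y, y)
        kv = m.select_knots(m.estimate_time_density(t), t)
        model = m.fit_penalized(track, kv, 1e12, 1e12)
        X = np.vstack([np.ones_like(t), t]).T
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        _, fitted = model.positions(t)
        assert np.abs(fitted - X @ beta).max() <= 1e-3

    def test_df_nonincreasing_in_lambda(self, sine_track):
        kv = m.select_knots(m.estimate_time_density(sine_track.times),
                            sine_track.times)
        dfs = [m.fit_penalized(sine_track, kv, lam, lam).df_lat
               for lam in (1e-6, 1e-3, 1.0, 1e3)]
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(dfs, dfs[1:]))

    def test_rss_nondecreasing_in_lambda(self, sine_track):
        kv = m.select_knots(m.estimate_time_density(sine_track.times),
                            sine_track.times)
        rss = []
        for lam in (1e-6, 1e-3, 1.0, 1e3):
            model = m.fit_penalized(sine_track, kv, lam, lam)
            _, fitted = model.positions(sine_track.times)
            rss.append(np.sum((fitted - sine_track.lat) ** 2))
        assert all(r2 >= r1 - 1e-9 for r1, r2 in zip(rss, rss[1:]))

    def test_fit_linear_in_observations(self, rng):
        t = np.linspace(0, 10, 50)
        y1 = rng.standard_normal(50)
        y2 = rng.standard_normal(50)
        kv = m.select_knots(m.estimate_time_density(t), t)

        def fitted(y):
            model = m.fit_penalized(m.Track("x", t, y, y), kv, 0.1, 0.1)
            return model.positions(t)[1]

        np.testing.assert_allclose(fitted(y1 + y2), fitted(y1) + fitted(y2),
                                   atol=1e-8)


class TestGcv:
    def test_formula_df_zero(self):
        assert _gcv_from_parts(1.0, 0.0, 100) == pytest.approx(1.0)

    def test_formula_half_df(self):
        assert _gcv_from_parts(0.5, 50.0, 100) == pytest.approx(2.0)

    def test_diverges_as_df_approaches_m(self):
        scores = [_gcv_from_parts(1.0, df, 100) for df in (90, 99, 99.9)]
        assert scores[0] < scores[1] < scores[2]
        with pytest.raises(ParameterError):
            _gcv_from_parts(1.0, 100.0, 100)

    def test_linear_denominator_variant(self):
        assert _gcv_from_parts(0.5, 50.0, 100, "linear") == pytest.approx(1.0)

    def test_gcv_score_endpoint(self, sine_track):
        kv = m.select_knots(m.estimate_time_density(sine_track.times),
                            sine_track.times)
        s = m.gcv_score(sine_track, kv, 1e-3, "lat")
        assert np.isfinite(s) and s > 0


class TestTuneSmoothing:
    def test_single_candidate_returned(self, sine_track):
        kv = m.select_knots(m.estimate_time_density(sine_track.times),
                            sine_track.times)
        trace = m.tune_smoothing(sine_track, kv, [0.5])
        assert trace.lambda_lat == 0.5 and trace.lambda_lon == 0.5

    def test_smooth_signal_selects_interior_lambda(self, rng):
        t = np.linspace(0, 10, 201)
        y = 0.5 * np.sin(2 * np.pi * t / 5) + 0.01 * rng.standard_normal(201)
        track = m.Track("s", t, y, y)
        kv = m.select_knots(m.estimate_time_density(t), t)
        trace = m.tune_smoothing(track, kv)
        assert trace.lambdas[0] < trace.lambda_lat < trace.lambdas[-1]

    def test_white_noise_selects_maximal_smoothing(self, rng):
        t = np.linspace(0, 10, 201)
        y = 1.0 + 0.2 * rng.standard_normal(201)
        track = m.Track("w", t, y, y)
        kv = m.select_knots(m.estimate_time_density(t), t)
        trace = m.tune_smoothing(track, kv)
        model = m.fit_penalized(track, kv, trace.lambda_lat, trace.lambda_lat)
        # maximal smoothing: essentially the penalty null space (a line)
        assert model.df_lat <= 2.5

    def test_equal_lambda_ties_coordinates(self, sine_track):
        kv = m.select_knots(m.estimate_time_density(sine_track.times),
                            sine_track.times)
        trace = m.tune_smoothing(sine_track, kv, [1e-4, 1e-2],
                                 equal_lambda=True)
        assert trace.lambda_lat == trace.lambda_lon


class TestEvaluation:
    def test_grid_point_count_10_days(self):
        grid = m.refined_grid((0.0, 10.0), 60.0)
        assert len(grid) == 241

    def test_interpolating_fit_matches_observations(self, rng):
        t = np.unique(np.sort(rng.uniform(0, 5, 30)))
        y = rng.standard_normal(len(t)) * 0.01
        track = m.Track("x", t, y, y)
        kv = m.KnotVector(t[1:-1], (t[0], t[-1]))
        model = m.fit_penalized(track, kv, 0.0, 0.0)
        _, _, lat = m.evaluate_path(model, t)
        assert np.abs(lat - y).max() <= 1e-6

    def test_no_extrapolation(self, sine_model):
        with pytest.raises(DomainError):
            m.evaluate_path(sine_model, np.array([-1.0]))

    def test_fine_grid_follows_same_path(self, sine_model):
        coarse = m.refined_grid(sine_model.domain, 60.0)
        fine = m.refined_grid(sine_model.domain, 1.0)
        _, _, lat_fine = m.evaluate_path(sine_model, fine)
        _, _, lat_coarse = m.evaluate_path(sine_model, coarse)
        interp = np.interp(fine, coarse, lat_coarse)
        # deviation bounded by curvature over one coarse step
        assert np.abs(lat_fine - interp).max() <= 1e-3

    def test_serialization_round_trip(self, sine_model):
        clone = m.SplineModel.from_json(sine_model.to_json())
        grid = m.refined_grid(sine_model.domain)
        np.testing.assert_allclose(clone.positions(grid)[1],
                                   sine_model.positions(grid)[1], atol=1e-12)


class TestDerivative:
    def test_constant_position_zero_derivative(self):
        from conftest import constant_model
        model = constant_model("c", 1.0, 2.0)
        _, dlat, dlon = m.path_derivative(model)
        np.testing.assert_allclose(dlat, 0.0, atol=1e-9)
        np.testing.assert_allclose(dlon, 0.0, atol=1e-9)

    def test_agrees_with_central_differences(self, sine_model):
        a, b = sine_model.domain
        grid = np.linspace(a + 0.01, b - 0.01, 400)
        dlat, _ = sine_model.derivatives(grid)
        eps = 1e-4
        fd = (sine_model.positions(grid + eps)[1]
              - sine_model.positions(grid - eps)[1]) / (2 * eps)
        assert np.abs(dlat - fd).max() <= 1e-5

    def test_linear_limit_constant_slope(self, rng):
        t = np.linspace(0, 10, 100)
        y = 2.0 + 0.5 * t + 0.01 * rng.standard_normal(100)
        track = m.Track("x", t, y, y)
        kv = m.select_knots(m.estimate_time_density(t), t)
        model = m.fit_penalized(track, kv, 1e12, 1e12)
        X = np.vstack([np.ones_like(t), t]).T
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        dlat, _ = model.derivatives(np.linspace(0.5, 9.5, 50))
        np.testing.assert_allclose(dlat, beta[1], atol=1e-6)
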
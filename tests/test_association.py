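"""Mutual information estimation and localized mutual information."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import movefda as m
from movefda.association import default_bins, equal_frequency_bins
from movefda.exceptions import ParameterError

from conftest import quick_fit


def diag_entropy(n: int, n_bins: int) -> float:
    """Entropy of the equal-frequency bin assignment of n distinct values."""
    counts = np.bincount(equal_frequency_bins(np.arange(n), n_bins),
                         minlength=n_bins).astype(float)
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


class TestMutualInformation:
    def test_perfect_dependence_equals_log_bins(self, rng):
        x = rng.standard_normal(1000)
        est = m.mutual_information(x, x, m.MiConfig(bins=8))
        assert est.value == pytest.approx(np.log(8), abs=1e-9)

    def test_perfect_dependence_default_bins(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        est = m.mutual_information(x, x)
        assert est.bins_or_k == default_bins(n)
        assert est.value == pytest.approx(diag_entropy(n, est.bins_or_k),
                                          abs=1e-9)

    def test_independent_uniforms_near_zero(self, rng):
        x, y = rng.random(10_000), rng.random(10_000)
        est = m.mutual_information(x, y)
        assert est.value <= 0.01

    def test_histogram_never_negative(self, rng):
        # plug-in MI is a KL divergence: nonnegative before any clamping
        for _ in range(10):
            est = m.mutual_information(rng.random(200), rng.random(200))
            assert est.raw_value >= 0.0

    def test_knn_cross_check_gaussian(self, rng):
        # KSG k-NN estimator against the bivariate-normal closed form
        rho = 0.9
        cov = [[1, rho], [rho, 1]]
        z = rng.multivariate_normal([0, 0], cov, 5000)
        analytic = -0.5 * np.log(1 - rho ** 2)
        knn = m.mutual_information(z[:, 0], z[:, 1],
                                   m.MiConfig(estimator="knn"))
        assert knn.value == pytest.approx(analytic, abs=0.1)
        hist = m.mutual_information(z[:, 0], z[:, 1])
        assert hist.value == pytest.approx(analytic, abs=0.15)

    def test_shuffling_destroys_dependence(self):
        n = 10_000
        wins = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(n)
            y = x + 0.3 * rng.standard_normal(n)
            aligned = m.mutual_information(x, y).value
            shuffled = m.mutual_information(x, rng.permutation(y)).value
            wins += aligned > shuffled
        assert wins >= trials - 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            m.mutual_information(np.arange(10.0), np.arange(11.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            m.mutual_information(np.arange(5.0), np.arange(5.0))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(10, 500), st.integers(2, 12))
    def test_equal_frequency_bins_balanced(self, n, n_bins):
        rng = np.random.default_rng(n * 31 + n_bins)
        counts = np.bincount(equal_frequency_bins(rng.random(n), n_bins),
                             minlength=n_bins)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == n


class TestLmiSeries:
    def test_exact_copy_reaches_perfect_dependence_value(self, sine_model):
        series = m.lmi_series(sine_model, sine_model)
        # interior windows hold 2*48+1 = 97 hourly samples
        w = 97
        expected = np.sqrt(2.0) * diag_entropy(w, default_bins(w))
        interior = (series.times >= series.times[0] + 2.0) & \
                   (series.times <= series.times[-1] - 2.0)
        assert series.defined[interior].all()
        np.testing.assert_allclose(series.raw[interior], expected, atol=1e-9)

    def test_independent_pair_low_median(self):
        medians = []
        pooled = []
        for seed in range(5):
            config = m.SimConfig(seed=seed, duration_days=60.0)
            a, b, _ = m.simulate_associated_pair(
                config, m.AssociationSchedule((), 0.0))
            series = m.lmi_series(quick_fit(a), quick_fit(b))
            pooled.append(series.raw[series.defined])
            medians.append(np.median(series.raw[series.defined]))
        assert np.median(np.concatenate(pooled)) <= 0.05

    def test_default_window_is_48_hours(self, sine_model):
        series = m.lmi_series(sine_model, sine_model)
        assert series.window_hours == 48.0

    def test_window_smaller_than_grid_spacing_rejected(self, sine_model):
        with pytest.raises(ParameterError):
            m.lmi_series(sine_model, sine_model, window_hours=0.5)

    def test_short_overlap_masked_undefined(self):
        from conftest import constant_model
        a = constant_model("a", 0.0, 0.0, domain=(0.0, 10.0))
        b = constant_model("b", 0.1, 0.0, domain=(9.9, 20.0))
        # overlap 0.1 day = 3 grid points < min_samples even with window
        series = m.lmi_series(a, b, config=m.MiConfig(min_samples=10))
        assert not series.defined.any()


class TestScaleLmi:
    def _series(self, raw, pair=("a", "b")):
        t = np.arange(len(raw), dtype=float)
        raw = np.asarray(raw, dtype=float)
        return m.LmiSeries(pair, t, 48.0, raw, np.isfinite(raw))

    def test_single_series_pointwise_is_unity(self):
        s = self._series([0.5, 1.0, 2.0])
        scaled = m.scale_lmi(s)
        np.testing.assert_allclose(scaled.scaled, 1.0)

    def test_dominant_series_scales_to_one(self):
        a = self._series([2.0, 4.0, 6.0])
        b = self._series([1.0, 1.0, 3.0], pair=("a", "c"))
        sa, sb = m.scale_lmi([a, b])
        np.testing.assert_allclose(sa.scaled, 1.0)
        np.testing.assert_allclose(sb.scaled, [0.5, 0.25, 0.5])

    def test_all_zero_scales_to_zero(self):
        s = self._series([0.0, 0.0])
        scaled = m.scale_lmi(s)
        np.testing.assert_allclose(scaled.scaled, 0.0)

    def test_global_max_policy(self):
        s = self._series([1.0, 2.0, 4.0])
        scaled = m.scale_lmi(s, policy="global-max")
        np.testing.assert_allclose(scaled.scaled, [0.25, 0.5, 1.0])

    def test_scaled_in_unit_interval_and_order_preserved(self, rng):
        a = self._series(rng.uniform(0, 3, 20))
        b = self._series(rng.uniform(0, 3, 20), pair=("a", "c"))
        sa, sb = m.scale_lmi([a, b])
        for s in (sa, sb):
            assert np.all((s.scaled >= 0) & (s.scaled <= 1))
        # within-time ordering across series preserved
        assert np.all((a.raw >= b.raw) == (sa.scaled >= sb.scaled))

    def test_mismatched_grids_rejected(self):
        a = self._series([1.0, 2.0])
        b = m.LmiSeries(("a", "c"), np.array([0.0, 0.5]), 48.0,
                        np.array([1.0, 2.0]), np.array([True, True]))
        with pytest.raises(ParameterError):
            m.scale_lmi([a, b])


class TestSummarizeWindow:
    def test_constant_distance_all_quantiles_equal(self):
        t = np.arange(0.0, 5.0, 1.0 / 24.0)
        dist = m.DistanceSeries(("a", "b"), t, np.full(len(t), 100.0))
        lmi = m.LmiSeries(("a", "b"), t, 48.0, np.linspace(0, 1, len(t)),
                          np.ones(len(t), dtype=bool))
        summary = m.summarize_window(dist, lmi, (1.0, 3.0))
        assert summary.distance_quantiles == (100.0,) * 5

    def test_five_number_summary(self):
        t = np.arange(5.0)
        dist = m.DistanceSeries(("a", "b"), t,
                                np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        lmi = m.LmiSeries(("a", "b"), t, 48.0, np.full(5, 0.5),
                          np.ones(5, dtype=bool))
        summary = m.summarize_window(dist, lmi, (0.0, 4.0))
        assert summary.distance_quantiles == (1.0, 2.0, 3.0, 4.0, 5.0)

    def test_empty_window_rejected(self):
        t = np.arange(5.0)
        dist = m.DistanceSeries(("a", "b"), t, np.ones(5))
        lmi = m.LmiSeries(("a", "b"), t, 48.0, np.ones(5),
                          np.ones(5, dtype=bool))
        with pytest.raises(m.WindowError):
            m.summarize_window(dist, lmi, (10.0, 12.0))
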
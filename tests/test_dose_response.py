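"""Spearman-Karber estimator: PAVA smoothing, trimming, median, variance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydratox.dose_response import (
    NotEstimableError,
    SmoothedCurve,
    estimate_lc50,
    estimate_lt50,
    extend_curve,
    pava,
    sk_confidence,
    sk_log_median,
    smooth_monotone,
    trim_curve,
)
from hydratox.records import DoseGroup, QuantalSeries, RunConfig

from conftest import random_monotone_curve


def exhaustive_isotonic(y, w):
    """Oracle: best monotone fit by enumerating contiguous-block partitions.

    Every weighted isotonic fit is piecewise constant on contiguous blocks at
    the blocks' weighted means; enumerate all 2^(k-1) partitions, keep the
    monotone ones, and return the weighted-SSE minimiser.
    """
    k = len(y)
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=k - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [k]
        fit = np.empty(k)
        means = []
        for lo, hi in zip(bounds, bounds[1:]):
            mu = np.average(y[lo:hi], weights=w[lo:hi])
            means.append(mu)
            fit[lo:hi] = mu
        if any(b < a - 1e-12 for a, b in zip(means, means[1:])):
            continue
        sse = float(np.sum(w * (y - fit) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = fit, sse
    return best


class TestPava:
    def test_equal_weight_violation_pooled(self):
        # (0, .6, .4, 1) -> the middle pair pools at its mean
        assert np.allclose(pava([0, 0.6, 0.4, 1], [10, 10, 10, 10]),
                           [0, 0.5, 0.5, 1])

    def test_weighted_pool_is_weighted_mean(self):
        # (6 + 6) dead of 40 -> 0.3 in both groups
        assert np.allclose(pava([0.6, 0.2], [10, 30]), [0.3, 0.3])

    def test_monotone_input_unchanged(self):
        y = np.array([0.0, 0.1, 0.1, 0.7, 1.0])
        assert np.array_equal(pava(y, np.full(5, 20.0)), y)

    def test_matches_exhaustive_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            k = int(rng.integers(2, 7))
            y = rng.uniform(0, 1, k)
            w = rng.integers(1, 40, k).astype(float)
            assert np.allclose(pava(y, w), exhaustive_isotonic(y, w), atol=1e-10)

    def test_matches_scipy_isotonic(self):
        from scipy.optimize import isotonic_regression

        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(2, 10))
            y = rng.uniform(0, 1, k)
            w = rng.uniform(0.5, 30, k)
            assert np.allclose(pava(y, w), isotonic_regression(y, weights=w).x,
                               atol=1e-10)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10),
           st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_idempotent_and_block_mean_conserving(self, y, wseed):
        rng = np.random.default_rng(wseed)
        y = np.asarray(y)
        w = rng.uniform(0.5, 20, len(y))
        fit = pava(y, w)
        assert np.all(np.diff(fit) >= -1e-12)
        assert np.allclose(pava(fit, w), fit, atol=1e-12)
        # weighted grand mean conserved (blocks preserve weighted means)
        assert np.isclose(np.average(fit, weights=w), np.average(y, weights=w))


class TestTrim:
    def test_zero_trim_identity(self, clean_series):
        curve = smooth_monotone(clean_series)
        assert trim_curve(curve, 0.0) is curve

    def test_crossings_interpolated(self):
        curve = SmoothedCurve(x=(1.0, 2.0, 3.0), p_raw=(0, 0.5, 1),
                              p_adj=(0.0, 0.5, 1.0), n=(20, 20, 20))
        out = trim_curve(curve, 0.1)
        assert np.allclose(out.x, (1.2, 2.0, 2.8))
        assert np.allclose(out.p_adj, (0.0, 0.5, 1.0))

    def test_unreachable_tail_not_estimable(self):
        curve = SmoothedCurve(x=(1.0, 2.0), p_raw=(0, 0.3), p_adj=(0.0, 0.3),
                              n=(20, 20))
        with pytest.raises(NotEstimableError):
            trim_curve(curve, 0.0)
        with pytest.raises(NotEstimableError):
            trim_curve(curve, 0.35)

    def test_trimmed_median_stable_on_symmetric_curve(self, clean_series):
        # trimming a symmetric response moves the median by very little
        curve = smooth_monotone(clean_series)
        m0 = sk_log_median(trim_curve(curve, 0.0))
        m1 = sk_log_median(trim_curve(curve, 0.15))
        assert abs(m0 - m1) < 0.02


class TestLogMedian:
    def test_symmetric_curve_gives_geometric_midpoint(self, clean_series):
        curve = smooth_monotone(clean_series)
        m = sk_log_median(curve)
        assert np.isclose(m, 2.150515, atol=1e-6)
        assert np.isclose(10 ** m, np.sqrt(100 * 200))

    def test_two_point_step(self):
        curve = SmoothedCurve(x=np.log10((1.0, 2.0)), p_raw=(0, 1),
                              p_adj=(0.0, 1.0), n=(20, 20))
        assert np.isclose(10 ** sk_log_median(curve), np.sqrt(2))

    def test_time_axis_hand_value(self):
        # times 12/24/48/72 hr with p (0,.25,.75,1): hand evaluation of the sum
        x = np.log10((12.0, 24.0, 48.0, 72.0))
        p = (0.0, 0.25, 0.75, 1.0)
        m = sk_log_median(SmoothedCurve(x=tuple(x), p_raw=p, p_adj=p, n=(20,) * 4))
        hand = (0.25 * (x[0] + x[1]) / 2 + 0.5 * (x[1] + x[2]) / 2
                + 0.25 * (x[2] + x[3]) / 2)
        assert np.isclose(m, hand, atol=1e-12)
        assert np.isclose(10 ** m, 32.7, atol=0.05)

    def test_trapezoid_identity_on_random_curves(self):
        # m == x_last - integral of p over x (summation by parts)
        rng = np.random.default_rng(99)
        for _ in range(300):
            c = random_monotone_curve(rng)
            m = sk_log_median(c)
            ident = c.x[-1] - np.trapezoid(c.p_adj, c.x)
            assert abs(m - ident) < 1e-9

    def test_unbracketed_curve_rejected(self):
        c = SmoothedCurve(x=(1.0, 2.0), p_raw=(0.2, 1.0), p_adj=(0.2, 1.0),
                          n=(20, 20))
        with pytest.raises(NotEstimableError):
            sk_log_median(c)


class TestConfidence:
    def test_hand_computed_variance_and_ci(self, clean_series):
        curve = smooth_monotone(clean_series)
        m = sk_log_median(curve)
        v, lo, hi = sk_confidence(curve, m, 0.95)
        assert np.isclose(v, 0.0015262, atol=2e-7)
        assert np.isclose(lo, 118.6, atol=0.1)
        assert np.isclose(hi, 168.7, atol=0.1)

    def test_degenerate_step_curve_zero_variance(self):
        c = SmoothedCurve(x=(1.0, 1.5, 2.0), p_raw=(0, 0, 1),
                          p_adj=(0.0, 0.0, 1.0), n=(20, 20, 20))
        m = sk_log_median(c)
        v, lo, hi = sk_confidence(c, m, 0.95)
        assert v == 0.0 and np.isclose(lo, hi) and np.isclose(lo, 10 ** m)

    def test_doubling_n_roughly_halves_variance(self, clean_series):
        curve = smooth_monotone(clean_series)
        m = sk_log_median(curve)
        v1, *_ = sk_confidence(curve, m)
        doubled = SmoothedCurve(x=curve.x, p_raw=curve.p_raw, p_adj=curve.p_adj,
                                n=tuple(2 * n for n in curve.n))
        v2, *_ = sk_confidence(doubled, m)
        # exact ratio is (n-1)/(2n-1), close to 1/2
        assert np.isclose(v2 / v1, 19 / 39)

    def test_interior_singleton_rejected(self):
        from hydratox.dose_response import VarianceUndefinedError

        c = SmoothedCurve(x=(1.0, 2.0, 3.0), p_raw=(0, 0.5, 1),
                          p_adj=(0.0, 0.5, 1.0), n=(20, 1, 20))
        with pytest.raises(VarianceUndefinedError):
            sk_confidence(c, sk_log_median(c), 0.95)

    def test_bootstrap_agrees_on_ci_width(self, clean_series):
        """Parametric bootstrap of the same design reproduces the CI width."""
        cfg = RunConfig(extend=True)
        base = estimate_lc50(clean_series, cfg)
        rng = np.random.default_rng(12345)
        p_true = np.array([0.0, 0.2, 0.8, 1.0])
        doses = np.array([50.0, 100.0, 200.0, 400.0])
        ms = []
        for _ in range(2000):
            dead = rng.binomial(20, p_true)
            groups = tuple(
                DoseGroup(d, 20, int(k)) for d, k in zip(doses, dead)
            )
            est = estimate_lc50(QuantalSeries(groups=groups, axis="dose"), cfg)
            if est.estimable:
                ms.append(est.m)
        boot_se = np.std(ms, ddof=1)
        assert abs(boot_se - base.se_log10) / boot_se < 0.15


class TestEstimatePipelines:
    def test_composition_equals_manual_stages(self, clean_series):
        est = estimate_lc50(clean_series, RunConfig(trim=0.05))
        curve = trim_curve(smooth_monotone(clean_series), 0.05)
        m = sk_log_median(curve)
        v, lo, hi = sk_confidence(curve, m, 0.95)
        assert est.m == m and est.variance == v
        assert est.ci_low == lo and est.ci_high == hi
        assert np.isclose(10 ** est.m, est.point)

    def test_all_zero_mortality_reported_not_estimable(self):
        groups = tuple(DoseGroup(d, 20, 0) for d in (50, 100, 200))
        est = estimate_lc50(QuantalSeries(groups=groups, axis="dose"))
        assert not est.estimable and est.point is None and est.reason

    def test_dose_scale_equivariance(self, clean_series):
        est1 = estimate_lc50(clean_series)
        scaled = QuantalSeries(
            groups=tuple(
                DoseGroup(g.dose * 7.5, g.n_exposed, g.n_dead)
                for g in clean_series.groups
            ),
            axis="dose",
        )
        est2 = estimate_lc50(scaled)
        assert np.isclose(est2.point, est1.point * 7.5)
        assert np.isclose(est2.ci_low, est1.ci_low * 7.5)

    def test_lt50_requires_time_axis_and_matches_hand_value(self):
        groups = tuple(
            DoseGroup(300, 20, d, time=t)
            for t, d in zip((12, 24, 48, 72), (0, 5, 15, 20))
        )
        series = QuantalSeries(groups=groups, axis="time", label="TGA 300")
        est = estimate_lt50(series)
        assert np.isclose(est.point, 32.7, atol=0.05)
        with pytest.raises(Exception):
            estimate_lt50(QuantalSeries(
                groups=tuple(DoseGroup(d, 20, k) for d, k in ((50, 0), (100, 20))),
                axis="dose"))

    def test_complete_mortality_at_first_time_not_estimable(self):
        groups = tuple(DoseGroup(500, 20, 20, time=t) for t in (24, 48, 72))
        est = estimate_lt50(QuantalSeries(groups=groups, axis="time"))
        assert not est.estimable

    def test_extension_rule_brackets_partial_curves(self):
        groups = tuple(
            DoseGroup(d, 20, k) for d, k in ((50, 2), (100, 6), (200, 14), (400, 18))
        )
        series = QuantalSeries(groups=groups, axis="dose")
        assert not estimate_lc50(series).estimable
        est = estimate_lc50(series, RunConfig(extend=True))
        assert est.estimable and est.ci_low < est.point < est.ci_high

    def test_extended_endpoints_one_log_step_out(self, clean_series):
        curve = smooth_monotone(clean_series)
        partial = SmoothedCurve(x=curve.x, p_raw=curve.p_raw,
                                p_adj=(0.1, 0.2, 0.8, 0.9), n=curve.n)
        ext = extend_curve(partial)
        step = np.mean(np.diff(curve.x))
        assert np.isclose(ext.x[0], curve.x[0] - step)
        assert np.isclose(ext.x[-1], curve.x[-1] + step)
        assert ext.p_adj[0] == 0.0 and ext.p_adj[-1] == 1.0
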
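"""Unit and property tests for the split-conformal calibration core."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metricbounds import (
    MetricEnsemble,
    MiscoverageRates,
    QuantileAdjustments,
    adjusted_levels,
    calibrate,
    empirical_quantile,
    nonconformity_scores,
    predict_interval,
)

from conftest import make_record


def sorted_oracle(values, level):
    """Independent brute force: sort, take the max(1, ceil(level*m))-th value."""
    s = sorted(values)
    m = len(s)
    k = max(1, math.ceil(round(level * m, 9)))
    return s[k - 1]


class TestEmpiricalQuantile:
    @pytest.mark.parametrize(
        "values, level, expected",
        [
            ([5, 5, 5], 0.3, 5),
            (list(range(1, 11)), 0.1, 1),
            (list(range(1, 11)), 0.9, 9),
            ([3, 1, 2], 1.0, 3),
            ([3, 1, 2], 0.0, 1),
            ([7.5], 0.5, 7.5),
        ],
    )
    def test_order_statistic_rule(self, values, level, expected):
        assert empirical_quantile(values, level) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty sample set"):
            empirical_quantile([], 0.5)

    def test_level_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            empirical_quantile([1.0], 1.5)

    def test_exhaustive_small_sets_match_oracle(self):
        """All sets of size <= 8 on a fine level grid agree with the sort oracle."""
        rng = np.random.default_rng(0)
        levels = np.linspace(0, 1, 101)
        for m in range(1, 9):
            for _ in range(25):
                values = rng.normal(size=m)
                for level in levels:
                    assert empirical_quantile(values, level) == sorted_oracle(
                        values, level
                    )

    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=30
        ),
        level=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_property_matches_oracle_and_is_an_element(self, values, level):
        q = empirical_quantile(values, level)
        assert q == sorted_oracle(values, level)
        assert q in values


class TestScoresAndLevels:
    def test_degenerate_ensemble_scores_zero(self, rates10):
        rec = make_record([4.0] * 6, 4.0)
        s = nonconformity_scores(rec, rates10)
        assert s.s_lo == 0.0 and s.s_hi == 0.0

    def test_signed_scores_from_formulas(self, rates10):
        rec = make_record(range(1, 11), 5.0)
        s = nonconformity_scores(rec, rates10)
        assert s.s_lo == -4.0 and s.s_hi == -4.0

    def test_truth_below_all_samples_gives_positive_lower_score(self):
        rec = make_record([10, 11, 12], 0.0)
        s = nonconformity_scores(rec, MiscoverageRates(0.05, 0.05))
        assert s.s_lo == 10.0

    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(596, 0.05, 29 / 596), (19, 0.05, 1 / 19), (100, 0.0, 0.0)],
    )
    def test_finite_sample_levels(self, n, alpha, expected):
        rates = MiscoverageRates(alpha, alpha)
        a_lo, a_hi = adjusted_levels(n, rates)
        assert a_lo == expected == a_hi

    def test_small_n_floors_to_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="metricbounds.conformal"):
            a_lo, a_hi = adjusted_levels(3, MiscoverageRates(0.1, 0.1))
        assert a_lo == 0.0 and a_hi == 0.0
        assert "too small" in caplog.text

    def test_nonpositive_n_rejected(self, rates10):
        with pytest.raises(ValueError):
            adjusted_levels(0, rates10)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            MiscoverageRates(0.6, 0.5)
        with pytest.raises(ValueError):
            MiscoverageRates(-0.1, 0.1)


class TestCalibrate:
    def test_empty_calibration_set_rejected(self, rates10):
        with pytest.raises(ValueError, match="empty calibration set"):
            calibrate([], rates10)

    def test_degenerate_records_give_zero_adjustments(self, rates10):
        records = [make_record([c] * 5, c) for c in (1.0, 2.0, 3.0)]
        adj = calibrate(records, rates10)
        assert adj.q_lo == 0.0 and adj.q_hi == 0.0
        assert adj.n == 3

    def test_small_n_adjustments_are_score_maxima(self):
        # n=3, alpha=0.05 -> alpha_hat=0 -> (1-0)-quantile = score maximum.
        # Hand-set scores: lower {-1, 0, 2}, upper {-2, 1, 1}.
        # single-sample ensembles make scores transparent:
        # s_lo = y_hat - truth, s_hi = truth - y_hat
        records = [
            make_record([1.0], 2.0),   # s_lo=-1, s_hi= 1
            make_record([5.0], 5.0),   # s_lo= 0, s_hi= 0
            make_record([9.0], 7.0),   # s_lo= 2, s_hi=-2
        ]
        adj = calibrate(records, MiscoverageRates(0.05, 0.05))
        assert adj.q_lo == 2.0  # max of {-1, 0, 2}
        assert adj.q_hi == 1.0  # max of {1, 0, -2}
        assert adj.alpha_hat_lo == 0.0 and adj.alpha_hat_hi == 0.0

    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_joint_shift_invariance_of_adjustments(self, shift):
        """Shifting every sample AND truth by c leaves (q_lo, q_hi) unchanged."""
        rates = MiscoverageRates(0.1, 0.1)
        rng = np.random.default_rng(5)
        records = [
            make_record(rng.normal(10, 2, 20), rng.normal(10, 2))
            for _ in range(8)
        ]
        shifted = [
            make_record(r.ensemble.values + shift, r.truth + shift)
            for r in records
        ]
        a, b = calibrate(records, rates), calibrate(shifted, rates)
        assert a.q_lo == pytest.approx(b.q_lo, abs=1e-9)
        assert a.q_hi == pytest.approx(b.q_hi, abs=1e-9)


class TestPredictInterval:
    def test_identity_adjustments_give_raw_quantiles(self, rates10):
        ens = MetricEnsemble("t", np.arange(1.0, 11.0))
        adj = QuantileAdjustments(0.0, 0.0, 0.1, 0.1, 9)
        iv = predict_interval(ens, adj, rates10)
        assert (iv.lower, iv.upper) == (1.0, 9.0)

    def test_adjustments_shift_each_endpoint(self, rates10):
        ens = MetricEnsemble("t", np.arange(1.0, 11.0))
        adj = QuantileAdjustments(0.5, 2.0, 0.1, 0.1, 9)
        iv = predict_interval(ens, adj, rates10)
        assert (iv.lower, iv.upper) == (0.5, 11.0)

    def test_single_sample_reduces_to_y_plus_minus_q(self, rates10):
        ens = MetricEnsemble("t", np.array([42.0]))
        adj = QuantileAdjustments(3.0, 1.0, 0.1, 0.1, 9)
        iv = predict_interval(ens, adj, rates10)
        assert (iv.lower, iv.upper) == (39.0, 43.0)

    def test_optional_domain_clamp(self, rates10):
        ens = MetricEnsemble("t", np.array([1.0, 2.0]))
        adj = QuantileAdjustments(10.0, 0.0, 0.1, 0.1, 9)
        free = predict_interval(ens, adj, rates10)
        clamped = predict_interval(ens, adj, rates10, domain=(0.0, np.inf))
        assert free.lower < 0 and clamped.lower == 0.0
        assert clamped.upper == free.upper

    def test_prediction_shift_invariance(self, rates10):
        """Adding b to all calibration samples and test samples (truths fixed)
        leaves the interval unchanged: the adjustments absorb the shift."""
        rng = np.random.default_rng(7)
        records = [
            make_record(rng.normal(10, 2, 20), rng.normal(10, 2))
            for _ in range(15)
        ]
        test = MetricEnsemble("t", rng.normal(10, 2, 20))
        b = 12.34
        shifted_records = [
            make_record(r.ensemble.values + b, r.truth) for r in records
        ]
        shifted_test = MetricEnsemble("t", test.values + b)
        iv = predict_interval(test, calibrate(records, rates10), rates10)
        iv_b = predict_interval(
            shifted_test, calibrate(shifted_records, rates10), rates10
        )
        assert iv_b.lower == pytest.approx(iv.lower, abs=1e-9)
        assert iv_b.upper == pytest.approx(iv.upper, abs=1e-9)

    def test_joint_shift_equivariance(self, rates10):
        """Shifting predictions AND truths by b shifts the interval by b."""
        rng = np.random.default_rng(8)
        records = [
            make_record(rng.normal(0, 1, 10), rng.normal(0, 1))
            for _ in range(12)
        ]
        test = MetricEnsemble("t", rng.normal(0, 1, 10))
        b = -4.5
        shifted = [
            make_record(r.ensemble.values + b, r.truth + b) for r in records
        ]
        iv = predict_interval(test, calibrate(records, rates10), rates10)
        iv_b = predict_interval(
            MetricEnsemble("t", test.values + b), calibrate(shifted, rates10), rates10
        )
        assert iv_b.lower == pytest.approx(iv.lower + b, abs=1e-9)
        assert iv_b.upper == pytest.approx(iv.upper + b, abs=1e-9)

    @pytest.mark.parametrize("side", ["lo", "hi"])
    def test_monotone_widening_as_alpha_decreases(self, side, small_pool):
        """Decreasing one mis-coverage rate never narrows the interval."""
        test = small_pool[-1].ensemble
        cal = small_pool[:-1]
        prev = None
        for a in (0.2, 0.1, 0.05, 0.02):
            rates = MiscoverageRates(
                alpha_lo=a if side == "lo" else 0.1,
                alpha_hi=a if side == "hi" else 0.1,
            )
            iv = predict_interval(test, calibrate(cal, rates), rates)
            if prev is not None:
                if side == "lo":
                    assert iv.lower <= prev.lower + 1e-12
                else:
                    assert iv.upper >= prev.upper - 1e-12
            prev = iv


def test_ensemble_validation():
    with pytest.raises(ValueError):
        MetricEnsemble("x", np.array([]))
    with pytest.raises(ValueError):
        MetricEnsemble("x", np.array([1.0, np.nan]))
    with pytest.raises(ValueError):
        make_record([1.0], np.inf)
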
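"""Rate estimators: closed forms, oracle agreement, recovery, CI behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluctassay.distribution import ld_loglik
from fluctassay.estimate import (
    FluctuationModel,
    estimate_auto,
    estimate_median_lc,
    estimate_mle,
    estimate_p0,
    lea_coulson_m,
    median_ci,
    rate_per_cell,
)
from fluctassay.exceptions import DomainError, MethodInapplicableError, ValidationError
from fluctassay.io import cultures_to_frame

from ._oracles import (
    bisect_median_equation,
    grid_argmax_loglik,
    median_ci_ranks_by_enumeration,
)
from .conftest import make_cultureset, simulate_set


class TestRatePerCell:
    def test_division(self):
        assert rate_per_cell(10, 1e8) == pytest.approx(1e-7)
        assert rate_per_cell(0, 1e8) == 0.0

    def test_proportionality(self):
        assert rate_per_cell(10, 2e8) == pytest.approx(rate_per_cell(10, 1e8) / 2)

    def test_invalid_nt(self):
        with pytest.raises(DomainError):
            rate_per_cell(1, 0)


class TestP0:
    def test_closed_form(self):
        cs = make_cultureset([0, 0, 3, 5, 1, 2, 9, 4, 6, 7])
        est = estimate_p0(cs)
        assert est.m_hat == pytest.approx(-math.log(0.2), rel=1e-12)
        assert est.mu_hat == pytest.approx(est.m_hat / 1e8, rel=1e-12)

    def test_all_zero(self):
        est = estimate_p0(make_cultureset([0] * 10))
        assert est.m_hat == 0.0
        assert est.ci_low <= 0 <= est.ci_high

    def test_no_zero_class_inapplicable(self):
        with pytest.raises(MethodInapplicableError):
            estimate_p0(make_cultureset([3, 5, 2]))

    def test_recovery_from_simulation(self):
        cs = simulate_set(1.0, 500, seed=31)
        est = estimate_p0(cs)
        p0 = math.exp(-1.0)
        se = math.sqrt((1 - p0) / (500 * p0))
        assert abs(est.m_hat - 1.0) < 3 * se

    def test_ci_brackets_estimate(self):
        cs = simulate_set(1.0, 100, seed=32)
        est = estimate_p0(cs)
        assert est.ci_low <= est.mu_hat <= est.ci_high


class TestMedianLc:
    def test_matches_bisection_oracle(self):
        for r in (1, 5, 30, 200):
            assert lea_coulson_m(r) == pytest.approx(bisect_median_equation(r), rel=1e-9)

    def test_known_root(self):
        # 30/m - ln m = 1.24 has its root near m = 8.8
        assert lea_coulson_m(30) == pytest.approx(8.8, abs=0.05)

    def test_monotone_in_median(self):
        assert lea_coulson_m(60) > lea_coulson_m(30)

    def test_zero_median_inapplicable(self):
        with pytest.raises(MethodInapplicableError):
            estimate_median_lc(make_cultureset([0, 0, 0, 1, 2, 0]))

    def test_recovery_from_simulation(self):
        """Median of m_hat over replicate experiments at m = 10 is within 25%."""
        m_hats = [
            estimate_median_lc(simulate_set(10.0, 18, seed=200 + i)).m_hat
            for i in range(100)
        ]
        assert abs(np.median(m_hats) - 10.0) / 10.0 < 0.25

    def test_ci_brackets_estimate_and_reports_coverage(self):
        cs = simulate_set(10.0, 18, seed=41)
        est = estimate_median_lc(cs)
        assert est.ci_low <= est.mu_hat <= est.ci_high
        assert est.achieved_confidence >= 0.95

    def test_per_culture_variant_orders_like_default(self):
        cs = simulate_set(5.0, 18, seed=42)
        a = estimate_median_lc(cs)
        b = estimate_median_lc(cs, per_culture=True)
        assert a.m_hat > 0 and b.m_hat > 0

    def test_scale_consistency(self):
        """Multiplying the true rate by k multiplies the recovered rate by ~k."""
        base = np.median(
            [estimate_auto(simulate_set(2.0, 72, seed=300 + i, strain_id="lo")).m_hat
             for i in range(30)]
        )
        scaled = np.median(
            [estimate_auto(simulate_set(20.0, 72, seed=300 + i, strain_id="hi")).m_hat
             for i in range(30)]
        )
        assert 10 / 1.5 < scaled / base < 10 * 1.5


class TestMle:
    def test_all_zero_boundary(self):
        est = estimate_mle(make_cultureset([0] * 12))
        assert est.m_hat == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0

    def test_matches_grid_search_oracle(self):
        counts = [5, 12, 0, 3]
        est = estimate_mle(make_cultureset(counts))
        grid = np.arange(0.05, 20.0, 0.05)
        best = grid_argmax_loglik(counts, grid, ld_loglik)
        assert abs(est.m_hat - best) <= 0.05

    def test_profile_ci_brackets_estimate(self):
        cs = simulate_set(5.0, 18, seed=51)
        est = estimate_mle(cs)
        assert est.ci_low < est.mu_hat < est.ci_high

    def test_tighter_than_median_method(self):
        """Head-to-head recovery: the MLE has smaller spread than the median
        method on the same replicate experiments."""
        mle_hats, med_hats = [], []
        for i in range(60):
            cs = simulate_set(10.0, 18, seed=400 + i)
            mle_hats.append(estimate_mle(cs).m_hat)
            med_hats.append(estimate_median_lc(cs).m_hat)
        mle_hats, med_hats = np.array(mle_hats), np.array(med_hats)
        assert abs(np.median(mle_hats) - 10) / 10 < 0.15
        assert np.std(np.log(mle_hats)) < np.std(np.log(med_hats))

    def test_jackpot_censoring_bounds_tabulation(self):
        counts = [3, 8, 1, 0, 5, 250_000]
        est = estimate_mle(make_cultureset(counts), jackpot_cap=1000)
        assert np.isfinite(est.m_hat) and est.m_hat > 0


class TestMedianCi:
    def test_ranks_n18(self):
        low, high, achieved = median_ci(np.arange(1, 19))
        assert (low, high) == (5, 14)
        assert achieved == pytest.approx(0.9691, abs=1e-4)

    @pytest.mark.parametrize("n", range(6, 40))
    def test_matches_binomial_enumeration(self, n):
        oracle = median_ci_ranks_by_enumeration(n)
        low, high, achieved = median_ci(np.arange(1, n + 1))
        assert (low, high) == (oracle[0], oracle[1])
        assert achieved == pytest.approx(oracle[2], abs=1e-12)

    def test_constant_vector(self):
        low, high, _ = median_ci([7.0] * 20)
        assert (low, high) == (7.0, 7.0)

    def test_small_n_inapplicable(self):
        with pytest.raises(MethodInapplicableError):
            median_ci([1, 2, 3, 4, 5])

    @given(st.integers(min_value=6, max_value=60))
    @settings(max_examples=20, deadline=None)
    def test_monotone_relabeling_equivariance(self, n):
        """A strictly monotone transform maps the interval endpoints."""
        rng = np.random.default_rng(n)
        v = rng.poisson(8.0, size=n).astype(float)
        lo, hi, _ = median_ci(v)
        lo2, hi2, _ = median_ci(np.exp(v / 10.0))
        assert lo2 == pytest.approx(np.exp(lo / 10.0))
        assert hi2 == pytest.approx(np.exp(hi / 10.0))


class TestEstimatorAgreement:
    @pytest.mark.parametrize("m", [0.5, 2.0, 10.0])
    def test_three_estimators_agree(self, m):
        """Median medians of p0/median/MLE estimates agree within MC spread."""
        results = {"p0": [], "median_lc": [], "mle": []}
        for i in range(40):
            cs = simulate_set(m, 30, seed=int(1000 * m) + i)
            results["mle"].append(estimate_mle(cs).m_hat)
            try:
                results["p0"].append(estimate_p0(cs).m_hat)
            except MethodInapplicableError:
                pass
            try:
                results["median_lc"].append(estimate_median_lc(cs).m_hat)
            except MethodInapplicableError:
                pass
        ref = np.median(results["mle"])
        for method, vals in results.items():
            if len(vals) >= 20:
                assert np.median(vals) == pytest.approx(ref, rel=0.35), method


class TestModelApi:
    def test_from_dataframe_and_summary(self, wt_set):
        df = cultures_to_frame([wt_set])
        model = FluctuationModel.from_dataframe(df)
        res = model.fit(method="median_lc")
        assert res.strain_id == wt_set.strain_id
        text = res.summary()
        assert "median_lc" in text and "mu (per cell)" in text

    def test_fit_dispatch_unknown_method(self, wt_set):
        with pytest.raises(ValidationError):
            FluctuationModel.from_cultureset(wt_set).fit(method="bogus")

    def test_loglik_delegates(self, wt_set):
        model = FluctuationModel.from_cultureset(wt_set)
        assert model.loglik(3.0) == pytest.approx(
            ld_loglik(wt_set.counts, 3.0, censor_at=10_000)
        )
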
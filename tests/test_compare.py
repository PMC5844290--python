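"""Strain comparison: rank-sum, fold change, mutator calls, dominance, synergy."""

import numpy as np
import pytest

from fluctassay.compare import (
    ComparisonResult,
    classify_mutator,
    dominance_analysis,
    fold_change,
    interaction_index,
    rank_sum_test,
    synergy_test,
)
from fluctassay.exceptions import UndefinedFoldError, ValidationError

from ._oracles import mann_whitney_exact_two_sided
from .conftest import make_cultureset, simulate_set


class TestRankSum:
    def test_identical_multisets(self):
        assert rank_sum_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_small_exact_enumeration(self):
        # all 6 rank assignments of {1,2} vs {3,4}: two are at least as extreme
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=5)
        y = rng.normal(0.8, 1, size=4)
        assert rank_sum_test(x, y) == pytest.approx(
            mann_whitney_exact_two_sided(x, y), rel=1e-9
        )

    def test_exact_vs_asymptotic_concordance(self):
        """For n = m = 8 tie-free samples the two computations agree closely."""
        rng = np.random.default_rng(77)
        diffs = []
        for _ in range(100):
            x = rng.normal(0, 1, size=8)
            y = rng.normal(0.5, 1, size=8)
            p_exact = rank_sum_test(x, y, method="exact")
            p_asym = rank_sum_test(x, y, method="asymptotic")
            diffs.append(abs(p_exact - p_asym))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1, 2])


class TestFoldChange:
    def test_self_comparison(self, wt_set):
        res = fold_change(wt_set, wt_set, n_boot=500, seed=1)
        assert res.fold == 1.0
        assert res.fold_ci[0] <= 1.0 <= res.fold_ci[1]
        assert res.p_value == pytest.approx(1.0)

    def test_deterministic_under_seed(self, wt_set):
        other = simulate_set(30.0, 18, seed=12, strain_id="mut")
        a = fold_change(other, wt_set, n_boot=500, seed=9)
        b = fold_change(other, wt_set, n_boot=500, seed=9)
        assert a.fold_ci == b.fold_ci

    def test_zero_reference_undefined(self):
        ref = make_cultureset([0] * 10, strain_id="null")
        cs = simulate_set(5.0, 18, seed=13, strain_id="mut")
        with pytest.raises(UndefinedFoldError):
            fold_change(cs, ref, n_boot=100, seed=0)

    def test_fold_recovery_at_10x(self, wt_set):
        """A strain simulated at 10x the reference recovers a fold in [5, 20]."""
        hits = 0
        for i in range(50):
            wt = simulate_set(3.0, 18, seed=5000 + i, strain_id="WT")
            mut = simulate_set(30.0, 18, seed=5000 + i, strain_id="mut")
            res = fold_change(mut, wt, n_boot=200, seed=i)
            hits += 5 <= res.fold <= 20
        assert hits / 50 >= 0.9

    def test_significance_direction(self, wt_set):
        mut = simulate_set(60.0, 18, seed=14, strain_id="mut")
        res = fold_change(mut, wt_set, n_boot=500, seed=2)
        assert res.fold > 1
        assert res.p_value < 0.05
        assert res.is_mutator


class TestClassifyMutator:
    def _result(self, fold, p):
        return ComparisonResult(
            strain_id="s", reference_id="WT", fold=fold, fold_ci=(0, 0),
            p_value=p, is_mutator=False,
        )

    @pytest.mark.parametrize(
        "fold, p, expected",
        [(2.0, 0.01, True), (2.0, 0.20, False), (0.5, 0.01, False)],
    )
    def test_rules(self, fold, p, expected):
        assert classify_mutator(self._result(fold, p)) is expected

    def test_monotone_in_alpha(self):
        res = self._result(2.0, 0.03)
        for hi, lo in [(0.05, 0.01), (0.2, 0.05), (0.04, 0.002)]:
            assert classify_mutator(res, lo) <= classify_mutator(res, hi)


class TestDominance:
    def test_ratio_arithmetic(self):
        # het at half the hom rate, strong signal: ratio ~ 0.5, semidominant
        wt = simulate_set(2.0, 24, seed=600, strain_id="WT/WT")
        het = simulate_set(40.0, 24, seed=601, strain_id="x/WT")
        hom = simulate_set(80.0, 24, seed=602, strain_id="x/x")
        res = dominance_analysis(wt, het, hom, n_boot=1000, seed=3)
        assert res.ratio == pytest.approx(0.5, abs=0.35)
        assert res.call == "semidominant"
        assert res.het_fold > 1 and res.hom_fold > res.het_fold

    def test_recessive_when_het_at_wild_type(self):
        calls = []
        for i in range(20):
            wt = simulate_set(2.0, 24, seed=700 + i, strain_id="WT/WT")
            het = simulate_set(2.0, 24, seed=800 + i, strain_id="x/WT")
            hom = simulate_set(80.0, 24, seed=900 + i, strain_id="x/x")
            calls.append(dominance_analysis(wt, het, hom, n_boot=500, seed=i).call)
        assert calls.count("recessive") >= 16

    def test_dominant_when_het_equals_hom(self):
        # ratio CI must resolve "above 0.75", which needs more cultures than
        # the semidominant call does
        calls = []
        for i in range(20):
            wt = simulate_set(2.0, 72, seed=1700 + i, strain_id="WT/WT")
            het = simulate_set(80.0, 72, seed=1800 + i, strain_id="x/WT")
            hom = simulate_set(80.0, 72, seed=1900 + i, strain_id="x/x")
            calls.append(dominance_analysis(wt, het, hom, n_boot=500, seed=i).call)
        assert calls.count("dominant") >= 14
        assert "recessive" not in calls

    def test_zero_homozygote_rejected(self):
        wt = simulate_set(2.0, 18, seed=1, strain_id="WT/WT")
        het = simulate_set(2.0, 18, seed=2, strain_id="x/WT")
        hom = make_cultureset([0] * 18, strain_id="x/x")
        with pytest.raises(UndefinedFoldError):
            dominance_analysis(wt, het, hom, n_boot=100, seed=0)


class TestSynergy:
    def test_multiplicative_arithmetic(self):
        assert interaction_index(3.0, 25.0, 75.0) == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            interaction_index(0.0, 25.0, 75.0)

    def _quartet(self, seed, ab_m):
        wt = simulate_set(2.0, 18, seed=seed, strain_id="WT")
        a = simulate_set(6.0, 18, seed=seed, strain_id="a")
        b = simulate_set(50.0, 18, seed=seed, strain_id="b")
        ab = simulate_set(ab_m, 18, seed=seed, strain_id="ab")
        return wt, a, b, ab

    def test_multiplicative_null_covered(self):
        # double mutant exactly at the multiplicative expectation:
        # folds 3 x 25 -> ab at 75x the wild-type m of 2
        covered = 0
        for i in range(25):
            res = synergy_test(*self._quartet(2000 + i, 150.0), n_boot=500, seed=i)
            covered += res.index_ci[0] <= 1.0 <= res.index_ci[1]
        assert covered >= 20

    def test_synergistic_call(self):
        # ab at 10x the multiplicative expectation
        calls = []
        for i in range(25):
            res = synergy_test(*self._quartet(3000 + i, 1500.0), n_boot=500, seed=i)
            calls.append(res.call)
        assert calls.count("synergistic") >= 20

    def test_null_panel_index_near_one(self):
        covered = 0
        for i in range(25):
            wt = simulate_set(3.0, 18, seed=4000 + i, strain_id="WT")
            a = simulate_set(3.0, 18, seed=4100 + i, strain_id="a")
            b = simulate_set(3.0, 18, seed=4200 + i, strain_id="b")
            ab = simulate_set(3.0, 18, seed=4300 + i, strain_id="ab")
            res = synergy_test(wt, a, b, ab, n_boot=500, seed=i)
            covered += res.index_ci[0] <= 1.0 <= res.index_ci[1]
        assert covered >= 20

    def test_transposition_symmetry(self):
        wt, a, b, ab = self._quartet(5000, 300.0)
        r1 = synergy_test(wt, a, b, ab, n_boot=400, seed=8)
        r2 = synergy_test(wt, b, a, ab, n_boot=400, seed=8)
        assert r1.interaction_index == pytest.approx(r2.interaction_index, rel=1e-12)
        assert r1.index_ci == pytest.approx(r2.index_ci, rel=1e-12)
        assert r1.call == r2.call

    def test_inestimable_arm_named(self):
        wt, a, b, ab = self._quartet(6000, 300.0)
        bad = make_cultureset([0, 0, 0, 0, 0, 1] * 3, strain_id="b0")
        with pytest.raises(ValidationError, match="b_only"):
            synergy_test(wt, a, bad, ab, n_boot=100, seed=0, estimator="median_lc")

    def test_zero_wild_type_rejected(self):
        wt, a, b, ab = self._quartet(6000, 300.0)
        null_wt = make_cultureset([0] * 18, strain_id="w0")
        with pytest.raises(UndefinedFoldError):
            synergy_test(null_wt, a, b, ab, n_boot=100, seed=0)
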
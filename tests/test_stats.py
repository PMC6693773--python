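"""Exact nonparametric tests, logistic prediction and CV machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ventmech.geometry import SyntheticCohortSpec, generate_synthetic_cohort
from ventmech.stats import (ConfusionCounts, cross_validate, evaluate_confusion,
                            fit_logistic_gd, roc_auc, spearman,
                            wilcoxon_rank_sum, wilcoxon_signed_rank,
                            _tof_predictor_arrays)


def brute_force_rank_sum_p(x, y):
    """Two-sided exact rank-sum p by full enumeration (oracle)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w_obs = ranks[: len(x)].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, len(x))]
    lo = np.mean([s <= w_obs + 1e-9 for s in sums])
    hi = np.mean([s >= w_obs - 1e-9 for s in sums])
    return min(1.0, 2 * min(lo, hi))


def brute_force_signed_rank_p(d):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    sums = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)]
    lo = np.mean([s <= w_obs + 1e-9 for s in sums])
    hi = np.mean([s >= w_obs - 1e-9 for s in sums])
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxonRankSum:
    def test_most_extreme_of_twenty_arrangements(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(3, 8, size=2)
        # integer draws produce ties, exercising the mid-rank path
        x = rng.integers(0, 6, size=nx).astype(float)
        y = rng.integers(0, 6, size=ny).astype(float) + rng.integers(0, 3)
        if np.all(np.concatenate([x, y]) == x[0]):
            return
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_fixture_bg_wg_end_ejection_significant(self, cohort):
        bg = [p.stress_2g["ee"] for p in cohort.by_group("BG")]
        wg = [p.stress_2g["ee"] for p in cohort.by_group("WG")]
        res = wilcoxon_rank_sum(bg, wg)
        assert res.p_value <= 0.05  # published p = 0.026


class TestWilcoxonSignedRank:
    def test_all_positive_differences_minimum_p(self):
        # 18 positive differences: the exact two-sided floor is 2 / 2^18
        res = wilcoxon_signed_rank(np.arange(1.0, 19.0))
        assert res.p_value == pytest.approx(2 * 0.5**18, rel=1e-9)

    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed_rank([+1, -1, +1, -1, +1, -1])
        assert res.p_value == 1.0

    def test_single_sign_flip_increases_p(self):
        d = np.arange(1.0, 19.0)
        p_all = wilcoxon_signed_rank(d).p_value
        d[0] = -d[0]
        assert wilcoxon_signed_rank(d).p_value > p_all

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(5, 9)
        d = rng.integers(-5, 6, size=n).astype(float)
        if np.all(d == 0):
            return
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_value == 1.0


class TestSpearman:
    def test_fixture_delta_ef_correlations(self, cohort):
        d = [p.delta_ef for p in cohort.tof]
        ef = [p.stress_2g["ef"] for p in cohort.tof]
        be = [p.stress_2g["be"] for p in cohort.tof]
        assert spearman(d, ef).statistic == pytest.approx(-0.650, abs=5e-4)
        assert spearman(d, be).statistic == pytest.approx(-0.608, abs=5e-4)

    def test_perfect_correlation(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_exact_permutation_matches_enumeration(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        assert res.method == "exact"
        # oracle: enumerate all 720 permutations of y's ranks
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
        obs = abs(np.dot(rx_c, ry_c))
        stats = [abs(np.dot(rx_c, ry_c[list(p)]))
                 for p in itertools.permutations(range(6))]
        expected = np.mean([s >= obs - 1e-12 for s in stats])
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestLogisticGD:
    def test_symmetric_data_zero_intercept(self):
        m = fit_logistic_gd([-1, -1, 1, 1], [0, 0, 1, 1])
        assert m.beta0 == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 8000
        w = rng.normal(size=n)
        logit = -1.0 + 2.0 * w
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        m = fit_logistic_gd(w, y, max_iter=30000)
        # model was fitted on the standardized scale; map coefficients back
        mu, sd = m.standardization
        b1 = m.beta1 / sd
        b0 = m.beta0 - m.beta1 * mu / sd
        assert b1 == pytest.approx(2.0, rel=0.10)
        assert b0 == pytest.approx(-1.0, rel=0.10)

    def test_fixture_stress_direction(self, cohort):
        w, y = _tof_predictor_arrays(cohort, "stress_2g_ee")
        m = fit_logistic_gd(w, y)
        assert m.beta1 < 0  # higher stress predicts the worse outcome

    def test_separation_capped(self):
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic_gd([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                max_iter=200000)
        assert abs(m.beta1) <= 25.0


class TestConfusionAndROC:
    @pytest.mark.parametrize("counts,expected", [
        ((3, 3, 0, 0), (1.0, 1.0, 1.0)),
        ((0, 6, 0, 6), (0.5, 0.0, 1.0)),   # degenerate always-negative
        ((2, 1, 1, 2), (0.5, 0.5, 0.5)),
    ])
    def test_confusion_examples(self, counts, expected):
        tp, tn, fp, fn = counts
        assert evaluate_confusion(ConfusionCounts(tp, tn, fp, fn)) == \
            pytest.approx(expected)

    def test_undefined_metric_is_none(self):
        acc, sens, spec = evaluate_confusion(ConfusionCounts(0, 4, 0, 0))
        assert sens is None and spec == 1.0

    def test_auc_examples(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)  # 3 of 4 pairs won
        _, auc = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert auc == 1.0

    def test_rank_auc_equals_trapezoid(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        points, auc = roc_auc(scores, labels)
        fpr, tpr = points[:, 0], points[:, 1]
        trap = np.trapezoid(tpr, fpr)
        assert auc == pytest.approx(trap, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCrossValidate:
    def test_reproducible_and_row_order_invariant(self, cohort):
        w, y = _tof_predictor_arrays(cohort, "stress_2g_ef")
        a = cross_validate(w, y, repeats=20, seed=5)
        b = cross_validate(w, y, repeats=20, seed=5)
        assert a.accuracy == b.accuracy and a.auc == b.auc

    def test_stable_across_seeds(self, cohort):
        w, y = _tof_predictor_arrays(cohort, "stress_2g_ef")
        accs = [cross_validate(w, y, repeats=50, seed=s).accuracy
                for s in range(3)]
        assert max(accs) - min(accs) < 0.06

    def test_null_synthetic_cohort_near_chance_auc(self):
        """With zero group effect, pooled CV AUC hovers around 0.5."""
        aucs = []
        for seed in range(4):
            cohort = generate_synthetic_cohort(
                SyntheticCohortSpec(n_per_group=6, group_effect=0.0, seed=seed))
            w, y = _tof_predictor_arrays(cohort, "stress_2g_ef")
            aucs.append(cross_validate(w, y, repeats=30, seed=seed).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15


class TestSyntheticCohortStatistics:
    def test_rank_sum_power_with_published_effect(self):
        """The published EF-stress group gap is detected in most replicates."""
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            cohort = generate_synthetic_cohort(
                SyntheticCohortSpec(n_per_group=6, group_effect=12.9, seed=seed))
            bg = [p.stress_2g["ef"] for p in cohort.by_group("BG")]
            wg = [p.stress_2g["ef"] for p in cohort.by_group("WG")]
            if wilcoxon_rank_sum(bg, wg).p_value <= 0.05:
                rejections += 1
        assert rejections / n_rep > 0.5

    def test_rank_sum_type_i_error_calibrated(self):
        """Null rejection rate stays inside the binomial band around the
        exact test's attainable level (alpha = 0.05, n = 6 vs 6)."""
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            cohort = generate_synthetic_cohort(
                SyntheticCohortSpec(n_per_group=6, group_effect=0.0,
                                    seed=10_000 + seed))
            bg = [p.stress_2g["ef"] for p in cohort.by_group("BG")]
            wg = [p.stress_2g["ef"] for p in cohort.by_group("WG")]
            if wilcoxon_rank_sum(bg, wg).p_value <= 0.05:
                rejections += 1
        # attainable level just below 0.05 for 6v6 exact test is ~0.041
        rate = rejections / n_rep
        level = 0.041
        band = 3 * math.sqrt(level * (1 - level) / n_rep)
        assert abs(rate - level) < band

    def test_determinism(self):
        spec = SyntheticCohortSpec(seed=42)
        a = generate_synthetic_cohort(spec).to_frame()
        b = generate_synthetic_cohort(spec).to_frame()
        assert a.equals(b)

    def test_generator_recovers_group_effect(self):
        spec = SyntheticCohortSpec(n_per_group=40, group_effect=12.9,
                                   noise_sd=9.0, seed=11)
        df = generate_synthetic_cohort(spec).to_frame()
        gap = df[df.group == "WG"].stress_2g_ef.mean() \
            - df[df.group == "BG"].stress_2g_ef.mean()
        assert abs(gap - 12.9) < 2 * 9.0 / math.sqrt(40)

    def test_delta_ef_negatively_associated_with_ef_stress(self):
        df = generate_synthetic_cohort(
            SyntheticCohortSpec(n_per_group=60, seed=2)).to_frame()
        rho = spearman(df.delta_ef_pct, df.stress_2g_ef)
        assert rho.statistic < -0.3
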
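import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from thinslice import (
    ConfusionCounts,
    PairedRatings,
    bootstrap_ci,
    delong_auc_test,
    diagnostic_metrics,
    diagnostic_rate_chisq,
    likert_noninferiority,
    mcnemar_test,
    permutation_test_f1,
    wilcoxon_signed_rank,
)
from thinslice.stats import binary_stat, round1


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def enumerate_signed_rank_p(diffs, alternative="two-sided"):
    """Oracle: exact Wilcoxon p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    sums = np.array(sums)
    p_ge = np.mean(sums >= obs - 1e-12)
    p_le = np.mean(sums <= obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def enumerate_permutation_p(pred_a, pred_b, truth, statistic="f1"):
    """Oracle: exact paired permutation p over all 2^n swap patterns."""
    n = len(truth)
    d_obs = binary_stat(pred_a, truth, statistic) - binary_stat(
        pred_b, truth, statistic
    )
    count = 0
    total = 0
    for swaps in itertools.product([False, True], repeat=n):
        sw = np.array(swaps)
        pa = np.where(sw, pred_b, pred_a)
        pb = np.where(sw, pred_a, pred_b)
        d = binary_stat(pa, truth, statistic) - binary_stat(pb, truth, statistic)
        count += abs(d) >= abs(d_obs) - 1e-12
        total += 1
    return count / total


def pair_counting_auc(scores, labels):
    """Oracle: AUC by exhaustive positive/negative pair counting."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Confusion metrics (worked examples from printed count pairs)
# ---------------------------------------------------------------------------


class TestDiagnosticMetrics:
    def test_reader_study_thick_slice_counts(self):
        m = diagnostic_metrics(ConfusionCounts(tp=38, fn=12, fp=3, tn=47))
        assert m["sensitivity"] == 76.0
        assert m["specificity"] == 94.0
        assert m["precision"] == 92.7
        assert m["accuracy"] == 85.0
        assert m["f1"] == 83.5

    def test_reader_study_synthetic_thin_counts(self):
        m = diagnostic_metrics(ConfusionCounts(tp=44, fn=6, fp=1, tn=49))
        assert m["f1"] == 92.6

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=20))
        for key in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert m[key] == 100.0

    def test_zero_denominator_flagged_not_crashed(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert m["sensitivity"] is None
        assert "sensitivity" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_rounding_half_away_from_zero(self):
        assert round1(83.45) == 83.5
        assert round1(83.4499) == 83.4
        assert round1(-83.45) == -83.5


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_branch_matches_enumeration(self, rng, alternative):
        for trial in range(6):
            n = int(rng.integers(5, 12))
            d = rng.normal(size=n)
            if trial % 2:  # force ties and zeros into some trials
                d = np.round(d * 2) / 2.0
            got = wilcoxon_signed_rank(d, alternative=alternative)
            if got["degenerate"]:
                continue
            expected = enumerate_signed_rank_p(d, alternative)
            assert got["p"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_degenerate(self):
        out = wilcoxon_signed_rank(np.zeros(8))
        assert out["degenerate"] and out["p"] == 1.0

    def test_large_n_uses_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(0.3, 1.0, size=60)
        got = wilcoxon_signed_rank(d)["p"]
        ref = scipy_wilcoxon(d, correction=True, method="approx").pvalue
        assert got == pytest.approx(ref, rel=1e-6)

    def test_unknown_alternative(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], alternative="both")


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


class TestMcNemar:
    def test_symmetric_discordance_is_nonsignificant(self):
        assert mcnemar_test(7, 7)["p"] >= 0.99

    def test_one_sided_discordance_exact_value(self):
        # binomial tail enumeration: 2 * (1/2)^10
        assert mcnemar_test(10, 0)["p"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_argument_order_invariance(self):
        assert mcnemar_test(3, 9)["p"] == mcnemar_test(9, 3)["p"]
        assert mcnemar_test(30, 12)["p"] == mcnemar_test(12, 30)["p"]

    def test_degenerate_no_discordance(self):
        out = mcnemar_test(0, 0)
        assert out["degenerate"] and out["p"] == 1.0

    def test_matches_statsmodels_exact_and_asymptotic(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(2, 9), (5, 5), (0, 12)]:
            table = [[0, b], [c, 0]]
            ref = sm.mcnemar(table, exact=True).pvalue
            assert mcnemar_test(b, c)["p"] == pytest.approx(ref, rel=1e-8)
        for b, c in [(30, 12), (40, 40)]:
            table = [[0, b], [c, 0]]
            ref = sm.mcnemar(table, exact=False, correction=True).pvalue
            assert mcnemar_test(b, c)["p"] == pytest.approx(ref, rel=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(-1, 2)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


class TestDeLong:
    def test_perfect_separation_auc_one(self):
        out = delong_auc_test([1, 2, 3, 7, 8, 9], [1, 1, 2, 2, 3, 3],
                              [0, 0, 0, 1, 1, 1])
        assert out["auc_a"] == 1.0

    def test_identical_scores_p_one(self):
        s = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        out = delong_auc_test(s, list(s), [0, 0, 1, 1, 1, 0])
        assert out["delta"] == 0.0 and out["p"] == 1.0

    def test_auc_matches_exhaustive_pair_counting(self, rng):
        for _ in range(8):
            n = int(rng.integers(6, 13))
            labels = np.zeros(n, dtype=int)
            labels[: n // 2] = 1
            rng.shuffle(labels)
            scores = np.round(rng.random(n), 1)  # induce ties
            out = delong_auc_test(scores, rng.random(n), labels)
            assert out["auc_a"] == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_tie_and_inversion_case(self):
        # 4 positives / 4 negatives with one tie and one inversion
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.3, 0.3, 0.2, 0.1, 0.4]
        out = delong_auc_test(scores, scores, labels)
        assert out["auc_a"] == pytest.approx(pair_counting_auc(scores, labels))

    def test_auc_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        scores = rng.random(30)
        out = delong_auc_test(scores, rng.random(30), labels)
        assert out["auc_a"] == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_auc_test([1, 2], [1, 2], [1, 1])


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


class TestPermutation:
    def test_identical_predictions_p_one(self):
        pred = [1, 0, 1, 1, 0, 0]
        truth = [1, 0, 0, 1, 0, 1]
        out = permutation_test_f1(pred, list(pred), truth, n_perm=500, seed=0)
        assert out["p"] == 1.0

    def test_seeded_reproducibility(self):
        a = [1, 1, 1, 0, 0, 0, 1, 0]
        b = [1, 0, 0, 0, 1, 0, 1, 1]
        t = [1, 1, 0, 0, 1, 0, 1, 0]
        p1 = permutation_test_f1(a, b, t, n_perm=2000, seed=11)["p"]
        p2 = permutation_test_f1(a, b, t, n_perm=2000, seed=11)["p"]
        assert p1 == p2

    @pytest.mark.parametrize("statistic", ["f1", "precision"])
    def test_matches_exhaustive_enumeration_n6(self, statistic):
        truth = [1, 1, 1, 0, 0, 0]
        pred_a = [1, 1, 1, 1, 0, 0]
        pred_b = [1, 0, 0, 0, 0, 1]
        exact = enumerate_permutation_p(
            np.array(pred_a), np.array(pred_b), np.array(truth), statistic
        )
        sampled = permutation_test_f1(
            pred_a, pred_b, truth, n_perm=20000, seed=3, statistic=statistic
        )["p"]
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_bad_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_f1([1], [0], [1], n_perm=0)


# ---------------------------------------------------------------------------
# Likert non-inferiority, chi-square, bootstrap
# ---------------------------------------------------------------------------


class TestLikertNoninferiority:
    def test_equal_ratings_are_noninferior(self):
        real = np.full(20, 4)
        out = likert_noninferiority(real, real.copy(), margin=0.25)
        # all shifted differences are +0.25: exact one-sided p = 2^-20
        assert out["p"] == pytest.approx(0.5**20, rel=1e-9)
        assert out["verdict"] == "non-inferior"

    def test_uniformly_worse_not_established(self):
        real = np.full(20, 4)
        out = likert_noninferiority(real, real - 1, margin=0.25)
        assert out["verdict"] == "not established"

    def test_zero_margin_equal_ratings_degenerate(self):
        real = np.full(10, 3)
        out = likert_noninferiority(real, real.copy(), margin=0.0)
        assert out["degenerate"]

    def test_paired_ratings_validation(self):
        with pytest.raises(ValueError):
            PairedRatings(real=np.array([1, 2]), synth=np.array([1, 6]))
        with pytest.raises(ValueError):
            PairedRatings(real=np.array([1, 2]), synth=np.array([1]))


class TestDiagnosticRateChisq:
    def test_identical_proportions_nonsignificant(self):
        assert diagnostic_rate_chisq((50, 50), (50, 50))["p"] == pytest.approx(1.0)

    def test_reader_study_quality_rates_highly_significant(self):
        # diagnostic-quality counts 634/640 vs 407/640
        out = diagnostic_rate_chisq((634, 6), (407, 233))
        assert out["p"] < 1e-10

    def test_argument_order_symmetry(self):
        a, b = (30, 10), (18, 22)
        assert diagnostic_rate_chisq(a, b)["p"] == diagnostic_rate_chisq(b, a)["p"]

    def test_small_expected_cells_use_exact_fallback(self):
        out = diagnostic_rate_chisq((1, 0), (0, 2))
        assert out["small_sample"] and out["method"] == "fisher-exact"


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.mean, np.full(30, 4.2), n_boot=200, seed=0)
        assert lo == hi == pytest.approx(4.2)

    def test_seeded_reproducibility(self, rng):
        data = rng.normal(size=40)
        assert bootstrap_ci(np.mean, data, n_boot=300, seed=5) == bootstrap_ci(
            np.mean, data, n_boot=300, seed=5
        )

    def test_coverage_near_nominal(self):
        """~95% of percentile CIs over Bernoulli(0.7) samples contain 0.7."""
        master = np.random.default_rng(2024)
        hits = 0
        n_sets = 200
        for i in range(n_sets):
            data = (master.random(60) < 0.7).astype(float)
            lo, hi = bootstrap_ci(np.mean, data, n_boot=200, seed=i)
            hits += lo <= 0.7 <= hi
        assert 0.90 <= hits / n_sets <= 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, [1.0], n_boot=10)
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, [], n_boot=200)
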
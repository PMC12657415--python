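"""ROC/Youden evaluation and nonparametric comparison tests."""

import numpy as np
import pytest

from explainstab import (
    bootstrap_metric,
    mann_whitney_u,
    roc_auc,
    wilcoxon_signed_rank,
    youden_threshold,
)


def auc_pair_oracle(scores, labels):
    """Enumerate all positive/negative pairs; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_scan_oracle(scores, labels):
    """Brute-force J over every distinct score threshold (rule: score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best = (-np.inf, None)
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        j = sens + spec - 1
        if j > best[0]:
            best = (j, t)
    return best


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pairs(self):
        # pairs: (.9,.8)+, (.9,.1)+, (.2,.8)-, (.2,.1)+ => 3/4
        assert roc_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = rng.binomial(1, 0.4, size=n)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces some ties
        assert roc_auc(scores, labels) == pytest.approx(auc_pair_oracle(scores, labels))


class TestYoudenThreshold:
    def test_perfect_separation_lowest_maximizer(self):
        t, j, sens, spec = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert j == 1.0
        assert t == 0.8  # lowest candidate achieving J=1 under score >= t

    def test_worked_example_tie_breaks_low(self):
        t, j, sens, spec = youden_threshold([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert j == pytest.approx(0.5)
        assert t == 0.4
        assert sens == 1.0 and spec == 0.5

    def test_uninformative_scores_give_zero_j(self):
        _, j, _, _ = youden_threshold([0.3] * 8, [1, 0] * 4)
        assert j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.binomial(1, 0.5, size=n)
        labels[:2] = [0, 1]
        scores = np.round(rng.beta(2, 2, size=n), 2)
        t, j, _, _ = youden_threshold(scores, labels)
        j_oracle, t_oracle = youden_scan_oracle(scores, labels)
        assert j == pytest.approx(j_oracle)
        assert t == pytest.approx(t_oracle)


class TestBootstrapMetric:
    def test_output_length(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=200)
        labels = rng.binomial(1, 0.5, size=200)
        out = bootstrap_metric(scores, labels, "auc", n_boot=100, seed=1)
        assert len(out) == 100

    def test_degenerate_perfect_classifier_all_ones(self):
        labels = np.array([1] * 20 + [0] * 20)
        scores = labels.astype(float)
        out = bootstrap_metric(scores, labels, "auc", n_boot=25, seed=2)
        assert np.all(out == 1.0)

    def test_replicate_mean_near_point_estimate(self):
        rng = np.random.default_rng(3)
        labels = rng.binomial(1, 0.5, size=400)
        scores = rng.normal(labels, 1.0)
        point = roc_auc(scores, labels)
        out = bootstrap_metric(scores, labels, "auc", n_boot=200, seed=4)
        assert abs(out.mean() - point) < 3 * out.std(ddof=1) / np.sqrt(len(out))

    def test_stratification_keeps_both_classes_with_rare_minority(self):
        rng = np.random.default_rng(5)
        labels = np.array([1] * 3 + [0] * 300)
        scores = rng.uniform(size=303)
        out = bootstrap_metric(scores, labels, "auc", n_boot=50, seed=6)
        assert np.isfinite(out).all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            bootstrap_metric([0.1, 0.9], [0, 1], "f1", n_boot=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        labels = rng.binomial(1, 0.5, size=100)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=100)
        a = bootstrap_metric(scores, labels, "sensitivity", n_boot=30, seed=8)
        b = bootstrap_metric(scores, labels, "sensitivity", n_boot=30, seed=8)
        np.testing.assert_array_equal(a, b)


class TestMannWhitneyU:
    def test_identical_samples_u_half_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value > 0.9

    def test_fully_separated_small_samples_exact_p(self):
        # U = 0 for a; all C(6,3)=20 rank splits, 2 * 1/20 = 0.1 two-sided
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.note == "exact"

    def test_p_invariant_to_sample_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, size=20)
        assert mann_whitney_u(a, b).p_value == pytest.approx(mann_whitney_u(b, a).p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_null_rejection_rate_calibrated(self):
        # type-I error at alpha=0.05 over many null replicates
        rng = np.random.default_rng(42)
        n_rep, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_rep):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            if mann_whitney_u(a, b).p_value < alpha:
                rejections += 1
        assert abs(rejections / n_rep - alpha) < 0.015


class TestWilcoxonSignedRank:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_uniformly_positive_differences_exact_p(self):
        # d = (+1, +2, +3): most extreme of the 2^3 sign patterns, p = 2/8
        res = wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(0.25)
        assert res.note == "exact"

    def test_swapping_sides_preserves_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        b = a + rng.normal(0.3, 1, size=30)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )

    def test_zeros_handled_by_pratt_not_errors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 8.0, 6.5])  # two zero differences
        res = wilcoxon_signed_rank(a, b)
        assert res.note == "asymptotic-pratt"
        assert 0.0 <= res.p_value <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])
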
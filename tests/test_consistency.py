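"""Top-k extraction, Jaccard and union-normalized Rank Agreement."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from explainstab import (
    TopKRanking,
    classwise_consistency,
    consistency_profile,
    jaccard_top_k,
    rank_agreement,
    top_k,
)
from explainstab.explainers.base import Explanation


def expl(values: dict, iid=0, method="shapley"):
    return Explanation(
        instance_id=iid, method=method,
        attribution=pd.Series(values, dtype=float), base=0.0, prediction=0.0,
    )


def ranking(names, k=None):
    names = tuple(names)
    return TopKRanking(features=names, k=k or len(names))


class TestTopK:
    def test_orders_by_absolute_attribution(self):
        e = expl({"age": 0.15, "cough": -0.2, "bmi": 0.1})
        assert top_k(e, 2).features == ("cough", "age")

    def test_k_beyond_p_returns_full_ordering(self):
        e = expl({"a": 0.3, "b": -0.5, "c": 0.1})
        assert top_k(e, 10).features == ("b", "a", "c")

    def test_ties_break_alphabetically_every_run(self):
        e = expl({"beta": 0.2, "alpha": -0.2, "gamma": 0.2})
        for _ in range(5):
            assert top_k(e, 3).features == ("alpha", "beta", "gamma")

    def test_zero_attributions_pad_ranking_and_flag_degenerate(self):
        e = expl({"a": 0.0, "b": 0.0, "c": 0.0})
        r = top_k(e, 2)
        assert len(r.features) == 2
        assert r.all_zero

    def test_signed_mode_ranks_raw_values(self):
        e = expl({"a": -0.9, "b": 0.5})
        assert top_k(e, 1, signed=True).features == ("b",)
        assert top_k(e, 1, signed=False).features == ("a",)


class TestMetricExamples:
    def test_worked_example_three_sevenths(self):
        r1 = ranking(("a", "b", "c", "d", "e"))
        r2 = ranking(("a", "f", "g", "d", "e"))
        assert jaccard_top_k(r1, r2) == pytest.approx(3 / 7)
        assert rank_agreement(r1, r2) == pytest.approx(3 / 7)

    def test_identical_rankings_score_one(self):
        r = ranking(("a", "b", "c"))
        assert jaccard_top_k(r, r) == 1.0
        assert rank_agreement(r, r) == 1.0

    def test_disjoint_rankings_score_zero(self):
        r1, r2 = ranking(("a", "b"), k=2), ranking(("c", "d"), k=2)
        assert jaccard_top_k(r1, r2) == 0.0
        assert rank_agreement(r1, r2) == 0.0

    def test_same_set_swapped_positions(self):
        # only 'a' keeps its position; union 3
        r1, r2 = ranking(("a", "b", "c")), ranking(("a", "c", "b"))
        assert rank_agreement(r1, r2) == pytest.approx(1 / 3)
        assert jaccard_top_k(r1, r2) == 1.0

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError, match="different k"):
            jaccard_top_k(ranking(("a",), k=1), ranking(("a", "b"), k=2))
        with pytest.raises(ValueError, match="different k"):
            rank_agreement(ranking(("a",), k=1), ranking(("a", "b"), k=2))


class TestMetricProperties:
    def test_brute_force_oracle_over_all_small_rankings(self):
        # enumerate every ordered ranking pair from a 5-feature universe (k=3)
        universe = "abcde"
        all_rankings = [ranking(p, k=3) for p in permutations(universe, 3)]
        for r1 in all_rankings[:20]:
            for r2 in all_rankings:
                s1, s2 = set(r1.features), set(r2.features)
                union = s1 | s2
                jac_oracle = len(s1 & s2) / len(union)
                ra_oracle = (
                    sum(1 for pos in range(3) if r1.features[pos] == r2.features[pos])
                    / len(union)
                )
                assert jaccard_top_k(r1, r2) == pytest.approx(jac_oracle)
                assert rank_agreement(r1, r2) == pytest.approx(ra_oracle)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_symmetry_bounds_and_ordering(self, data):
        universe = [f"f{i}" for i in range(8)]
        k = data.draw(st.integers(1, 5))
        r1 = ranking(tuple(data.draw(st.permutations(universe)))[:k], k=k)
        r2 = ranking(tuple(data.draw(st.permutations(universe)))[:k], k=k)
        j, ra = jaccard_top_k(r1, r2), rank_agreement(r1, r2)
        assert 0.0 <= ra <= j <= 1.0
        assert j == pytest.approx(jaccard_top_k(r2, r1))
        assert ra == pytest.approx(rank_agreement(r2, r1))

    def test_invariance_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        vals = dict(zip("abcdef", rng.normal(size=6)))
        e1, e2 = expl(vals), expl({k: 7.3 * v for k, v in vals.items()})
        assert top_k(e1, 4).features == top_k(e2, 4).features


class TestConsistencyProfile:
    def _pair(self, n=5, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        names = [f"f{i}" for i in range(6)]
        ref = [expl(dict(zip(names, rng.normal(size=6))), iid=i) for i in range(n)]
        tst = (
            ref
            if identical
            else [expl(dict(zip(names, rng.normal(size=6))), iid=i) for i in range(n)]
        )
        return ref, tst

    def test_self_comparison_mean_one_se_zero(self):
        ref, _ = self._pair(identical=True)
        res = consistency_profile(ref, ref, k=3)
        assert res.mean("jaccard") == 1.0 and res.mean("rank_agreement") == 1.0
        assert res.se("jaccard") == 0.0

    def test_rank_agreement_never_exceeds_jaccard_per_instance(self):
        ref, tst = self._pair(n=50, seed=3)
        res = consistency_profile(ref, tst, k=3)
        assert np.all(res.rank_agreement <= res.jaccard + 1e-12)

    def test_se_is_sd_over_sqrt_n(self):
        ref, tst = self._pair(n=100, seed=4)
        res = consistency_profile(ref, tst, k=3)
        assert res.se("jaccard") == pytest.approx(res.jaccard.std(ddof=1) / 10)

    def test_orphan_instances_rejected_with_listing(self):
        ref, tst = self._pair(n=4)
        tst = tst[:-1] + [expl({"f0": 1.0}, iid=99)]
        with pytest.raises(ValueError, match="99"):
            consistency_profile(ref, tst, k=2)

    def test_tidy_output_schema(self):
        ref, tst = self._pair(n=5, seed=6)
        res = consistency_profile(ref, tst, k=3, comparison="10% vs balanced")
        frame = res.to_frame()
        assert set(frame.columns) == {"comparison", "class", "metric", "instance_id", "value"}
        assert len(frame) == 2 * 5
        assert frame["value"].between(0, 1).all()


class TestClasswiseConsistency:
    def _explanations(self, n_per_class=6, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"f{i}" for i in range(6)]
        ids = list(range(2 * n_per_class))
        labels = {i: int(i < n_per_class) for i in ids}
        ref = [expl(dict(zip(names, rng.normal(size=6))), iid=i) for i in ids]
        tst = [expl(dict(zip(names, rng.normal(size=6))), iid=i) for i in ids]
        return ref, tst, labels

    def test_labels_and_sizes_attached(self):
        ref, tst, labels = self._explanations(n_per_class=6)
        minority, majority = classwise_consistency(ref, tst, labels, k=3, n_per_class=4, seed=1)
        assert minority.class_label == "minority" and majority.class_label == "majority"
        assert minority.n == 4 and majority.n == 4

    def test_identical_lists_score_one_in_both_classes(self):
        ref, _, labels = self._explanations()
        minority, majority = classwise_consistency(ref, ref, labels, k=3, n_per_class=5, seed=2)
        assert minority.mean("jaccard") == 1.0
        assert majority.mean("rank_agreement") == 1.0

    def test_single_class_input_rejected_with_counts(self):
        ref, tst, labels = self._explanations()
        labels = {k: 0 for k in labels}  # no minority instances at all
        with pytest.raises(ValueError, match="class 1 has only 0"):
            classwise_consistency(ref, tst, labels, k=3, n_per_class=2, seed=0)
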
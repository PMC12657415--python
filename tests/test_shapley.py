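"""Shapley attribution: value function, exact and sampled estimators, axioms."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from explainstab import (
    FunctionModel,
    global_importance,
    shapley_exact,
    shapley_sampled,
    value_function,
)
from explainstab.explainers.base import Explanation

from conftest import make_continuous_cohort, make_mixed_cohort


def permutation_oracle(model, instance, background):
    """Average marginal contribution over ALL p! feature orderings.

    Independent brute-force route: p! * p calls to value_function, no shared
    code with the combinatorial estimator beyond v itself.
    """
    names = [f.name for f in background.features]
    phi = {n: 0.0 for n in names}
    orderings = list(permutations(names))
    for order in orderings:
        prefix = []
        v_prev = value_function(model, instance, prefix, background)
        for name in order:
            prefix = prefix + [name]
            v_next = value_function(model, instance, prefix, background)
            phi[name] += v_next - v_prev
            v_prev = v_next
    return {n: phi[n] / len(orderings) for n in names}


class TestValueFunction:
    def test_full_coalition_is_model_prediction(self, continuous_cohort):
        model = FunctionModel(lambda X: X[:, 0] ** 2 + X[:, 1], continuous_cohort.features)
        inst = continuous_cohort.frame.iloc[3]
        v = value_function(model, inst, ["x1", "x2", "x3"], continuous_cohort)
        assert v == pytest.approx(inst["x1"] ** 2 + inst["x2"])

    def test_empty_coalition_is_background_mean(self, continuous_cohort):
        model = FunctionModel(lambda X: np.tanh(X).sum(axis=1), continuous_cohort.features)
        inst = continuous_cohort.frame.iloc[0]
        expected = np.tanh(continuous_cohort.frame.to_numpy()).sum(axis=1).mean()
        assert value_function(model, inst, [], continuous_cohort) == pytest.approx(expected)

    def test_two_row_background_hand_enumerated(self):
        cohort = make_continuous_cohort(n=2, p=2, seed=5)
        model = FunctionModel(lambda X: X[:, 0] * X[:, 1], cohort.features)
        inst = pd.Series({"x1": 2.0, "x2": 3.0})
        # substitute x1=2 into both background rows, average 2 * x2^(b)
        x2 = cohort.frame["x2"].to_numpy()
        assert value_function(model, inst, ["x1"], cohort) == pytest.approx(
            (2.0 * x2[0] + 2.0 * x2[1]) / 2
        )

    def test_unknown_feature_rejected(self, continuous_cohort):
        model = FunctionModel(lambda X: X[:, 0], continuous_cohort.features)
        with pytest.raises(KeyError, match="zz"):
            value_function(model, continuous_cohort.frame.iloc[0], ["zz"], continuous_cohort)


class TestShapleyExact:
    def test_constant_model_all_zero(self, continuous_cohort):
        model = FunctionModel(lambda X: np.full(len(X), 0.37), continuous_cohort.features)
        e = shapley_exact(model, continuous_cohort.frame.iloc[1], continuous_cohort)
        assert np.allclose(e.attribution.to_numpy(), 0.0, atol=1e-12)
        assert e.base == pytest.approx(0.37)

    def test_linear_model_closed_form(self, continuous_cohort):
        beta = np.array([0.4, -0.7, 0.2])
        model = FunctionModel(lambda X: 0.1 + X @ beta, continuous_cohort.features)
        inst = continuous_cohort.frame.iloc[2]
        e = shapley_exact(model, inst, continuous_cohort)
        expected = beta * (inst.to_numpy() - continuous_cohort.frame.mean().to_numpy())
        np.testing.assert_allclose(e.attribution.to_numpy(), expected, atol=1e-10)

    def test_matches_permutation_oracle_nonlinear(self):
        cohort = make_continuous_cohort(n=8, p=3, seed=3)
        model = FunctionModel(
            lambda X: np.sin(X[:, 0]) + X[:, 1] * X[:, 2] + 0.5 * X[:, 2] ** 2,
            cohort.features,
        )
        inst = cohort.frame.iloc[4]
        e = shapley_exact(model, inst, cohort)
        oracle = permutation_oracle(model, inst, cohort)
        for name in oracle:
            assert e.attribution[name] == pytest.approx(oracle[name], abs=1e-10)

    def test_efficiency_identity(self):
        cohort = make_continuous_cohort(n=15, p=4, seed=6)
        model = FunctionModel(lambda X: 1.0 / (1.0 + np.exp(-X.sum(axis=1))), cohort.features)
        e = shapley_exact(model, cohort.frame.iloc[0], cohort)
        assert abs(e.efficiency_gap()) < 1e-8

    def test_symmetry_of_interchangeable_features(self):
        # two features with identical role, identical instance and background values
        cohort = make_continuous_cohort(n=10, p=3, seed=7)
        cohort.frame["x2"] = cohort.frame["x1"]
        model = FunctionModel(lambda X: X[:, 0] + X[:, 1] + 0.3 * X[:, 2], cohort.features)
        e = shapley_exact(model, cohort.frame.iloc[5], cohort)
        assert e.attribution["x1"] == pytest.approx(e.attribution["x2"], abs=1e-10)

    def test_feature_cap_enforced(self):
        cohort = make_continuous_cohort(n=5, p=3, seed=8)
        model = FunctionModel(lambda X: X.sum(axis=1), cohort.features)
        with pytest.raises(ValueError, match="shapley_sampled"):
            shapley_exact(model, cohort.frame.iloc[0], cohort, max_features=2)

    def test_mixed_types_substitute_whole_categorical_blocks(self):
        cohort = make_mixed_cohort(n=30, seed=9)
        # model keyed to the one-hot block of 'grade'
        model = FunctionModel(lambda X: 0.2 + 0.5 * X[:, 1] + 0.1 * X[:, 3], cohort.features)
        e = shapley_exact(model, cohort.frame.iloc[0], cohort)
        assert abs(e.efficiency_gap()) < 1e-8
        assert list(e.attribution.index) == ["age", "grade", "flag"]


class TestShapleySampled:
    def test_constant_model_zero_any_seed(self, continuous_cohort):
        model = FunctionModel(lambda X: np.full(len(X), 0.8), continuous_cohort.features)
        for seed in (0, 1, 99):
            e = shapley_sampled(
                model, continuous_cohort.frame.iloc[0], continuous_cohort,
                n_permutations=5, seed=seed,
            )
            assert np.allclose(e.attribution.to_numpy(), 0.0, atol=1e-12)

    def test_many_permutations_converge_to_exact(self):
        cohort = make_continuous_cohort(n=6, p=4, seed=10)
        model = FunctionModel(lambda X: np.exp(0.3 * X[:, 0]) + X[:, 1] * X[:, 3], cohort.features)
        inst = cohort.frame.iloc[1]
        exact = shapley_exact(model, inst, cohort)
        sampled = shapley_sampled(model, inst, cohort, n_permutations=3000, seed=0)
        np.testing.assert_allclose(
            sampled.attribution.to_numpy(), exact.attribution.to_numpy(), atol=0.02
        )

    def test_efficiency_holds_per_construction(self):
        cohort = make_continuous_cohort(n=12, p=5, seed=11)
        model = FunctionModel(lambda X: np.tanh(X).prod(axis=1), cohort.features)
        e = shapley_sampled(model, cohort.frame.iloc[2], cohort, n_permutations=3, seed=4)
        assert abs(e.efficiency_gap()) < 1e-10

    def test_monte_carlo_error_shrinks_with_permutations(self):
        cohort = make_continuous_cohort(n=8, p=3, seed=12)
        model = FunctionModel(lambda X: np.sin(X).sum(axis=1) * X[:, 0], cohort.features)
        inst = cohort.frame.iloc[3]
        spreads = {}
        for n_perm in (10, 1000):
            estimates = [
                shapley_sampled(model, inst, cohort, n_permutations=n_perm, seed=s)
                .attribution["x1"]
                for s in range(15)
            ]
            spreads[n_perm] = np.std(estimates)
        # ~1/sqrt(n): expect ~10x reduction, assert at least 3x
        assert spreads[1000] < spreads[10] / 3

    def test_deterministic_under_seed(self, continuous_cohort):
        model = FunctionModel(lambda X: (X**2).sum(axis=1), continuous_cohort.features)
        inst = continuous_cohort.frame.iloc[0]
        e1 = shapley_sampled(model, inst, continuous_cohort, n_permutations=20, seed=5)
        e2 = shapley_sampled(model, inst, continuous_cohort, n_permutations=20, seed=5)
        pd.testing.assert_series_equal(e1.attribution, e2.attribution)


class TestGlobalImportance:
    def test_hand_arithmetic(self):
        def expl(vals):
            return Explanation(
                instance_id=None, method="shapley",
                attribution=pd.Series(vals, index=["a", "b"]), base=0.0, prediction=0.0,
            )

        imp = global_importance([expl([1.0, -1.0]), expl([3.0, 1.0])])
        assert imp["a"] == pytest.approx(2.0)
        assert imp["b"] == pytest.approx(1.0)

    def test_order_invariant_and_nonnegative(self):
        rng = np.random.default_rng(0)
        expls = [
            Explanation(
                instance_id=i, method="shapley",
                attribution=pd.Series(rng.normal(size=3), index=["a", "b", "c"]),
                base=0.0, prediction=0.0,
            )
            for i in range(5)
        ]
        fwd = global_importance(expls)
        rev = global_importance(expls[::-1])
        pd.testing.assert_series_equal(fwd, rev)
        assert (fwd >= 0).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            global_importance([])
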
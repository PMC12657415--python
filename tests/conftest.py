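import numpy as np
import pandas as pd
import pytest

from explainstab import Cohort, CohortSpec, FeatureSpec


def continuous_features(names=("x1", "x2", "x3")):
    return tuple(FeatureSpec(name=n, kind="continuous") for n in names)


def make_continuous_cohort(n=20, p=3, seed=0, outcome_rate=0.5):
    """Small all-continuous cohort; the workhorse background for explainer tests."""
    rng = np.random.default_rng(seed)
    names = [f"x{i + 1}" for i in range(p)]
    frame = pd.DataFrame(rng.normal(size=(n, p)), columns=names)
    outcome = rng.binomial(1, outcome_rate, size=n)
    if outcome.min() == outcome.max():  # both classes present for splitting ops
        outcome[0] = 1 - outcome[0]
    return Cohort(frame=frame, outcome=outcome, features=continuous_features(names))


def make_labeled_cohort(n_minority, n_majority, seed=0):
    """Cohort with exact class counts and one filler feature (for subset arithmetic)."""
    rng = np.random.default_rng(seed)
    n = n_minority + n_majority
    frame = pd.DataFrame({"x": rng.normal(size=n)})
    outcome = np.concatenate([np.ones(n_minority, dtype=int), np.zeros(n_majority, dtype=int)])
    return Cohort(frame=frame, outcome=outcome, features=continuous_features(("x",)))


def make_mixed_cohort(n=40, seed=0):
    """Cohort with one continuous, one 3-level categorical and one binary feature."""
    rng = np.random.default_rng(seed)
    levels = ("low", "mid", "high")
    frame = pd.DataFrame(
        {
            "age": rng.normal(60, 10, size=n),
            "grade": rng.choice(np.array(levels, dtype=object), size=n),
            "flag": rng.binomial(1, 0.3, size=n),
        }
    )
    features = (
        FeatureSpec(name="age", kind="continuous"),
        FeatureSpec(name="grade", kind="categorical", levels=levels, effect=(0.0, 0.0, 0.0)),
        FeatureSpec(name="flag", kind="binary"),
    )
    return Cohort(frame=frame, outcome=rng.binomial(1, 0.5, size=n), features=features)


def flat_spec(n_features=2, target=0.5, intercept=0.0, n=100):
    """Spec with zero effects everywhere (closed-form prevalence = logistic(c))."""
    feats = tuple(
        FeatureSpec(name=f"x{i + 1}", kind="continuous", effect=(0.0,))
        for i in range(n_features)
    )
    return CohortSpec(features=feats, target_prevalence=target, intercept=intercept, n=n)


@pytest.fixture
def continuous_cohort():
    return make_continuous_cohort()


@pytest.fixture
def mixed_cohort():
    return make_mixed_cohort()
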
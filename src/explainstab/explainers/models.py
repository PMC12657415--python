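"""Black-box model adapters.

An adapter is anything exposing

* ``fit(cohort)``               — train on a :class:`~explainstab.cohort.Cohort`;
* ``predict(frame)``            — positive-class probability per raw-feature row;
* ``predict_matrix(X)``         — same, on the one-hot encoded design matrix
                                   (columns in the cohort's encoded order);
* ``features``                  — the feature schema seen at fit time.

Explainers only require the encoded entry point, which lets them substitute
feature values in bulk without repeated dataframe construction.
"""

from __future__ import annotations

from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from ..cohort import Cohort, FeatureSpec, encode_frame

__all__ = ["ModelAdapter", "SupervisedAdapter", "FunctionModel", "model_adapter_registry"]


@runtime_checkable
class ModelAdapter(Protocol):
    features: tuple[FeatureSpec, ...]

    def fit(self, cohort: Cohort) -> "ModelAdapter": ...

    def predict(self, frame: pd.DataFrame) -> np.ndarray: ...

    def predict_matrix(self, X: np.ndarray) -> np.ndarray: ...


class SupervisedAdapter:
    """Wrap any scikit-learn-style classifier with ``predict_proba``."""

    def __init__(self, estimator, name: str = "model"):
        self.estimator = estimator
        self.name = name
        self.features: tuple[FeatureSpec, ...] = ()
        self._positive_col: int | None = None

    def fit(self, cohort: Cohort) -> "SupervisedAdapter":
        self.features = cohort.features
        X = cohort.encode().to_numpy(dtype=float)
        y = cohort.outcome
        self.estimator.fit(X, y)
        classes = list(getattr(self.estimator, "classes_", [0, 1]))
        self._positive_col = classes.index(1) if 1 in classes else None
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        if self._positive_col is None:  # degenerate: trained on one class
            p = np.zeros(len(X), dtype=float)
        else:
            p = proba[:, self._positive_col]
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        if not self.features:
            raise RuntimeError("adapter is not fitted")
        X = encode_frame(frame, self.features).to_numpy(dtype=float)
        return self.predict_matrix(X)

    def constructor_args(self) -> dict:
        """Exact estimator parameters, recorded in run manifests."""
        get = getattr(self.estimator, "get_params", None)
        return {k: repr(v) for k, v in (get() if get else {}).items()}


class FunctionModel:
    """Adapter around an explicit function of the encoded design matrix.

    The workhorse of the explainer test oracles: closed-form models (linear,
    constant, indicator) whose exact Shapley values / surrogate coefficients
    are known analytically.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], features: Sequence[FeatureSpec]):
        self.fn = fn
        self.features = tuple(features)

    def fit(self, cohort: Cohort) -> "FunctionModel":
        self.features = cohort.features
        return self

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(np.asarray(X, dtype=float)), dtype=float)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.predict_matrix(encode_frame(frame, self.features).to_numpy(dtype=float))


def model_adapter_registry() -> dict[str, Callable[[int], SupervisedAdapter]]:
    """Named constructors for the model roster.

    Tree ensembles use ``max_depth=5`` with otherwise-default parameters; the
    multilayer perceptron runs at library defaults; plain logistic regression
    is included as the analytically tractable workhorse.  Each constructor
    takes a seed so stochastic trainers are reproducible.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from xgboost import XGBClassifier

    def logistic(seed: int) -> SupervisedAdapter:
        return SupervisedAdapter(LogisticRegression(max_iter=2000), name="logistic")

    def random_forest(seed: int) -> SupervisedAdapter:
        return SupervisedAdapter(
            RandomForestClassifier(max_depth=5, random_state=seed, n_jobs=1),
            name="random_forest",
        )

    def xgboost(seed: int) -> SupervisedAdapter:
        return SupervisedAdapter(
            XGBClassifier(max_depth=5, random_state=seed, n_jobs=1, verbosity=0),
            name="xgboost",
        )

    def mlp(seed: int) -> SupervisedAdapter:
        return SupervisedAdapter(MLPClassifier(random_state=seed), name="mlp")

    return {
        "logistic": logistic,
        "random_forest": random_forest,
        "xgboost": xgboost,
        "mlp": mlp,
    }


def build_model(name: str, seed: int = 0) -> SupervisedAdapter:
    registry = model_adapter_registry()
    try:
        ctor = registry[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(registry)}"
        ) from None
    return ctor(seed)
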
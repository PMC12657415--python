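"""Shared types for the explanation methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Explanation", "explanations_to_frame", "explanations_to_csv", "explanations_from_csv"]


@dataclass
class Explanation:
    """Per-instance feature attribution produced by one explanation method.

    ``attribution`` maps each *original* feature name (not one-hot column) to
    its attributed contribution: surrogate coefficients for LIME, Shapley
    values for SHAP-style explanations.  ``base`` is the method's reference
    output (the surrogate intercept for LIME; the background-mean prediction
    ``E[f(X)]`` for Shapley values) and ``prediction`` is ``f(x)`` for the
    explained instance.
    """

    instance_id: object
    method: str
    attribution: pd.Series
    base: float
    prediction: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.attribution = pd.Series(self.attribution, dtype=float)
        if self.attribution.index.duplicated().any():
            raise ValueError("duplicate feature names in attribution")

    @property
    def feature_names(self) -> list[str]:
        return list(self.attribution.index)

    def efficiency_gap(self) -> float:
        """``sum(attribution) - (prediction - base)``.

        Zero (to numerical precision) for exact Shapley values — the
        additivity that lets a prediction be decomposed feature by feature.
        """
        return float(self.attribution.sum() - (self.prediction - self.base))


def explanations_to_frame(explanations: Sequence[Explanation]) -> pd.DataFrame:
    """Tidy long-format view: instance_id, method, feature, attribution, ..."""
    rows = []
    for e in explanations:
        for feat, val in e.attribution.items():
            rows.append(
                {
                    "instance_id": e.instance_id,
                    "method": e.method,
                    "feature": feat,
                    "attribution": val,
                    "base_value": e.base,
                    "prediction": e.prediction,
                }
            )
    return pd.DataFrame(rows)


def explanations_to_csv(explanations: Sequence[Explanation], path: str | Path) -> None:
    explanations_to_frame(explanations).to_csv(path, index=False)


def explanations_from_csv(path: str | Path) -> list[Explanation]:
    frame = pd.read_csv(path)
    out = []
    for (iid, method), grp in frame.groupby(["instance_id", "method"], sort=False):
        out.append(
            Explanation(
                instance_id=iid,
                method=method,
                attribution=pd.Series(
                    grp["attribution"].to_numpy(), index=grp["feature"].to_numpy()
                ),
                base=float(grp["base_value"].iloc[0]),
                prediction=float(grp["prediction"].iloc[0]),
            )
        )
    return out


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
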
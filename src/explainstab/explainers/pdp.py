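"""Partial dependence profiles.

The partial dependence of the model output on a feature x_S is the average
prediction when every background row is forced to carry the same value of
x_S while its remaining features stay at their observed values:

    pdp(v) = (1/n) * sum_i f(v, x_C^{(i)})

For categorical features the profile is evaluated once per declared level
(every row forced to the same category), in the declared level order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..cohort import Cohort, encoded_columns
from .models import ModelAdapter

__all__ = ["PDPCurve", "pdp_continuous", "pdp_categorical", "quantile_grid"]


@dataclass
class PDPCurve:
    """Averaged model output along a feature grid."""

    feature: str
    grid: list
    mean_prediction: np.ndarray
    n_background: int
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.mean_prediction = np.asarray(self.mean_prediction, dtype=float)
        if len(self.grid) != len(self.mean_prediction):
            raise ValueError("grid and mean_prediction lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "grid_value_or_level": self.grid,
                "mean_prediction": self.mean_prediction,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _column_offsets(features) -> dict[str, tuple[int, int]]:
    out = {}
    start = 0
    for f in features:
        width = len(encoded_columns(f))
        out[f.name] = (start, start + width)
        start += width
    return out


def pdp_continuous(
    model: ModelAdapter,
    background: Cohort,
    feature: str,
    grid: Sequence[float],
) -> PDPCurve:
    """Partial dependence of a continuous feature over an explicit grid."""
    spec = background.feature(feature)  # raises KeyError when unknown
    if spec.kind != "continuous":
        raise ValueError(f"feature {feature!r} is {spec.kind}, not continuous")
    grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    bg = background.encode().to_numpy(dtype=float)
    lo, hi = _column_offsets(background.features)[feature]
    means = np.empty(grid.size, dtype=float)
    for i, v in enumerate(grid):
        X = bg.copy()
        X[:, lo] = v
        means[i] = float(model.predict_matrix(X).mean())
    return PDPCurve(
        feature=feature,
        grid=list(grid),
        mean_prediction=means,
        n_background=background.n,
        kind="continuous",
    )


def pdp_categorical(model: ModelAdapter, background: Cohort, feature: str) -> PDPCurve:
    """Partial dependence over the declared level set of a categorical feature."""
    spec = background.feature(feature)
    if spec.kind not in ("categorical", "binary"):
        raise ValueError(f"feature {feature!r} is {spec.kind}, not categorical")
    if spec.kind == "binary":
        levels: list = [0, 1]
    else:
        levels = list(spec.levels)
        if not levels:
            raise ValueError(f"feature {feature!r} declares no levels")
    bg = background.encode().to_numpy(dtype=float)
    lo, hi = _column_offsets(background.features)[feature]
    means = np.empty(len(levels), dtype=float)
    for i, lvl in enumerate(levels):
        X = bg.copy()
        if spec.kind == "binary":
            X[:, lo] = float(lvl)
        else:
            X[:, lo:hi] = 0.0
            if i > 0:  # level 0 is the all-zero reference encoding
                X[:, lo + i - 1] = 1.0
        means[i] = float(model.predict_matrix(X).mean())
    return PDPCurve(
        feature=feature,
        grid=levels,
        mean_prediction=means,
        n_background=background.n,
        kind=spec.kind,
    )


def quantile_grid(background: Cohort, feature: str, n_points: int = 20) -> np.ndarray:
    """Evenly spaced quantiles of the background distribution of a feature."""
    spec = background.feature(feature)
    if spec.kind != "continuous":
        raise ValueError(f"feature {feature!r} is {spec.kind}, not continuous")
    qs = np.linspace(0.0, 1.0, n_points)
    return np.unique(np.quantile(background.frame[feature].to_numpy(dtype=float), qs))
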
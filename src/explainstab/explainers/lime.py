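"""LIME-style local surrogate explanations for tabular models.

A black-box model f is explained at an instance x by fitting a weighted
ridge regression g to f's predictions on a cloud Z of perturbed samples
around x, with proximity weights pi_x concentrating the fit near x:

    g = argmin sum_{z in Z} pi_x(z) (f(z) - g(z))^2 + lambda * ||beta||^2

Perturbation and surrogate representation (tabular conventions):

* continuous features are standardized against the background sample and
  perturbed with unit-variance Gaussian noise around the instance; the
  surrogate sees the standardized value;
* categorical and binary features are resampled from the background's
  empirical marginal; the surrogate sees an indicator for "equals the
  instance's value", so a feature's coefficient reads as the effect of
  matching the explained instance on that feature;
* proximity is an exponential kernel exp(-D^2 / w^2) on Euclidean distance
  in that same representation, default width 0.75 * sqrt(d).

The weighted ridge problem is solved in closed form (penalty on the
non-intercept coefficients only); the first perturbation is the instance
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..cohort import Cohort, encode_frame
from .base import Explanation
from .models import ModelAdapter

__all__ = ["LimeConfig", "lime_explain"]


@dataclass(frozen=True)
class LimeConfig:
    """Settings of the local surrogate fit.

    kernel_width ``None`` means the conventional default ``0.75 * sqrt(d)``
    where d is the surrogate representation's dimension (one column per
    feature).  ``ridge_penalty`` may be 0, in which case a singular weighted
    design is reported as an error rather than silently regularized.
    """

    n_perturbations: int = 1000
    kernel_width: float | None = None
    ridge_penalty: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturbations < 2:
            raise ValueError("n_perturbations must be >= 2")
        if self.kernel_width is not None and not self.kernel_width > 0:
            raise ValueError("kernel_width must be > 0")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")


def lime_explain(
    model: ModelAdapter,
    instance: pd.Series,
    background: Cohort,
    config: LimeConfig = LimeConfig(),
    instance_id=None,
) -> Explanation:
    """Fit the local weighted-ridge surrogate and return its coefficients."""
    if background.n == 0:
        raise ValueError("background must be nonempty")
    features = background.features
    names = [f.name for f in features]
    p = len(names)
    if config.n_perturbations < p + 2:
        raise ValueError(
            f"n_perturbations={config.n_perturbations} too small for {p} features "
            f"(need >= {p + 2})"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_perturbations

    inst = dict(instance)
    # Perturbed raw samples; row 0 is the instance itself.
    raw_cols: dict[str, np.ndarray] = {}
    rep_cols: list[np.ndarray] = []  # surrogate representation, one col/feature
    stats: dict[str, tuple[float, float]] = {}
    for f in features:
        bg_col = background.frame[f.name]
        if f.kind == "continuous":
            mu = float(bg_col.mean())
            sd = float(bg_col.std(ddof=0)) or 1.0
            stats[f.name] = (mu, sd)
            z_x = (float(inst[f.name]) - mu) / sd
            z = z_x + rng.standard_normal(n)
            z[0] = z_x
            raw_cols[f.name] = mu + sd * z
            rep_cols.append(z)
        else:
            pool = bg_col.to_numpy()
            draw = rng.choice(pool, size=n, replace=True)
            draw[0] = inst[f.name]
            raw_cols[f.name] = draw
            rep_cols.append((draw == inst[f.name]).astype(float))

    Z_frame = pd.DataFrame(raw_cols)
    M = np.column_stack(rep_cols)  # (n, p) surrogate representation
    m_x = M[0]

    width = config.kernel_width if config.kernel_width is not None else 0.75 * np.sqrt(p)
    d2 = ((M - m_x) ** 2).sum(axis=1)
    w = np.exp(-d2 / width**2)

    y = model.predict_matrix(encode_frame(Z_frame, features).to_numpy(dtype=float))

    # Weighted ridge via normal equations; intercept unpenalized.
    A = np.column_stack([np.ones(n), M])
    AtW = A.T * w
    lhs = AtW @ A
    pen = np.eye(p + 1) * config.ridge_penalty
    pen[0, 0] = 0.0
    lhs = lhs + pen
    rhs = AtW @ y
    try:
        if config.ridge_penalty == 0.0 and np.linalg.matrix_rank(lhs) < p + 1:
            raise np.linalg.LinAlgError("rank-deficient weighted design")
        beta = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        raise ValueError(
            "weighted design is singular with ridge_penalty=0; set a small "
            "positive ridge_penalty (e.g. 1e-6)"
        ) from None

    return Explanation(
        instance_id=instance_id,
        method="lime",
        attribution=pd.Series(beta[1:], index=names),
        base=float(beta[0]),
        prediction=float(y[0]),
        meta={
            "kernel_width": float(width),
            "n_perturbations": n,
            "ridge_penalty": config.ridge_penalty,
            "seed": config.seed,
            "standardization": stats,
        },
    )
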
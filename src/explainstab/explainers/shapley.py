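"""Shapley-value attributions with a marginal (interventional) value function.

A coalition S of features is evaluated by substituting the explained
instance's values for the features in S into every row of a background
sample and averaging the model output:

    v(S) = (1/B) * sum_b f(x_S, x_C^{(b)})

i.e. absent features are marginalized over the background's empirical
distribution.  The Shapley value of feature i weights its marginal
contribution v(S ∪ {i}) − v(S) over all coalitions not containing i by
|S|! (p − |S| − 1)! / p!.

Two estimators are provided: exhaustive coalition enumeration (exact, for
p up to a configurable cap) and a Monte-Carlo average over uniformly sampled
feature orderings, which is unbiased and satisfies the efficiency identity
sum(phi) = f(x) − E[f(X)] exactly for every sampled permutation (the prefix
contributions telescope).

Categorical features are substituted as whole features: the instance's level
replaces the background level, i.e. the feature's entire one-hot block moves
together, so attributions live at the original-feature level.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from ..cohort import Cohort, encode_frame, encoded_columns
from .base import Explanation
from .models import ModelAdapter

__all__ = [
    "value_function",
    "shapley_exact",
    "shapley_sampled",
    "global_importance",
    "EXACT_FEATURE_CAP",
]

EXACT_FEATURE_CAP = 12  # 2^p coalition evaluations beyond this is desk-hostile

_CHUNK_ROWS = 200_000  # cap on rows per model call when batching coalitions


def _encoded_blocks(features) -> list[np.ndarray]:
    """Per-feature boolean masks over the encoded design-matrix columns."""
    sizes = [len(encoded_columns(f)) for f in features]
    d = sum(sizes)
    blocks = []
    start = 0
    for s in sizes:
        m = np.zeros(d, dtype=bool)
        m[start : start + s] = True
        blocks.append(m)
        start += s
    return blocks


def _prepare(model: ModelAdapter, instance: pd.Series, background: Cohort):
    if background.n == 0:
        raise ValueError("background must be nonempty")
    features = background.features
    x_enc = encode_frame(pd.DataFrame([dict(instance)]), features).to_numpy(dtype=float)[0]
    bg_enc = background.encode().to_numpy(dtype=float)
    return features, x_enc, bg_enc, _encoded_blocks(features)


def _feature_mask_to_columns(mask: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    col = np.zeros(len(blocks[0]), dtype=bool)
    for j in np.flatnonzero(mask):
        col |= blocks[j]
    return col


def _coalition_means(
    model: ModelAdapter,
    x_enc: np.ndarray,
    bg_enc: np.ndarray,
    col_masks: np.ndarray,
) -> np.ndarray:
    """Mean model output per coalition column-mask, batched across coalitions."""
    B, d = bg_enc.shape
    m = len(col_masks)
    means = np.empty(m, dtype=float)
    per_chunk = max(1, _CHUNK_ROWS // B)
    for start in range(0, m, per_chunk):
        chunk = col_masks[start : start + per_chunk]  # (c, d)
        X = np.where(chunk[:, None, :], x_enc[None, None, :], bg_enc[None, :, :])
        preds = model.predict_matrix(X.reshape(-1, d)).reshape(len(chunk), B)
        means[start : start + per_chunk] = preds.mean(axis=1)
    return means


def value_function(
    model: ModelAdapter,
    instance: pd.Series,
    coalition,
    background: Cohort,
) -> float:
    """Marginal-expectation value of one coalition of feature names."""
    features, x_enc, bg_enc, blocks = _prepare(model, instance, background)
    names = [f.name for f in features]
    coalition = list(coalition)
    unknown = set(coalition) - set(names)
    if unknown:
        raise KeyError(f"coalition contains unknown feature(s): {sorted(unknown)}")
    fmask = np.array([n in coalition for n in names])
    cmask = _feature_mask_to_columns(fmask, blocks)
    return float(_coalition_means(model, x_enc, bg_enc, cmask[None, :])[0])


def _model_prediction(model: ModelAdapter, x_enc: np.ndarray) -> float:
    return float(model.predict_matrix(x_enc[None, :])[0])


def shapley_exact(
    model: ModelAdapter,
    instance: pd.Series,
    background: Cohort,
    max_features: int = EXACT_FEATURE_CAP,
    instance_id=None,
) -> Explanation:
    """Exact Shapley values by enumerating all 2^p coalitions (memoized)."""
    features, x_enc, bg_enc, blocks = _prepare(model, instance, background)
    names = [f.name for f in features]
    p = len(names)
    if p > max_features:
        raise ValueError(
            f"{p} features exceeds the exact-mode cap of {max_features}; "
            "use shapley_sampled for larger feature sets"
        )
    # v for every subset, indexed by bitmask
    fmasks = np.zeros((2**p, p), dtype=bool)
    for s in range(2**p):
        for j in range(p):
            fmasks[s, j] = bool(s >> j & 1)
    cmasks = np.stack([_feature_mask_to_columns(m, blocks) for m in fmasks])
    v = _coalition_means(model, x_enc, bg_enc, cmasks)

    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p, dtype=float)
    others = list(range(p))
    for i in range(p):
        rest = [j for j in others if j != i]
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for S in combinations(rest, size):
                s_bits = sum(1 << j for j in S)
                phi[i] += w * (v[s_bits | (1 << i)] - v[s_bits])
    base = float(v[0])
    prediction = float(v[2**p - 1])
    return Explanation(
        instance_id=instance_id,
        method="shapley",
        attribution=pd.Series(phi, index=names),
        base=base,
        prediction=prediction,
        meta={"estimator": "exact", "n_background": background.n},
    )


def shapley_sampled(
    model: ModelAdapter,
    instance: pd.Series,
    background: Cohort,
    n_permutations: int = 200,
    seed: int = 0,
    instance_id=None,
) -> Explanation:
    """Monte-Carlo Shapley values over uniformly sampled feature orderings.

    For each sampled permutation the marginal contributions along the prefix
    chain are accumulated; their sum telescopes to f(x) − E[f(X)], so the
    efficiency identity holds by construction for any number of permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    features, x_enc, bg_enc, blocks = _prepare(model, instance, background)
    names = [f.name for f in features]
    p = len(names)
    rng = np.random.default_rng(seed)

    # Build prefix coalition column-masks for all permutations, deduplicated.
    mask_index: dict[bytes, int] = {}
    col_masks: list[np.ndarray] = []

    def mask_id(fmask: np.ndarray) -> int:
        key = fmask.tobytes()
        idx = mask_index.get(key)
        if idx is None:
            idx = len(col_masks)
            mask_index[key] = idx
            col_masks.append(_feature_mask_to_columns(fmask, blocks))
        return idx

    perms = [rng.permutation(p) for _ in range(n_permutations)]
    chains: list[list[int]] = []
    for perm in perms:
        fmask = np.zeros(p, dtype=bool)
        chain = [mask_id(fmask)]
        for j in perm:
            fmask = fmask.copy()
            fmask[j] = True
            chain.append(mask_id(fmask))
        chains.append(chain)

    v = _coalition_means(model, x_enc, bg_enc, np.stack(col_masks))

    phi = np.zeros(p, dtype=float)
    for perm, chain in zip(perms, chains):
        for k, j in enumerate(perm):
            phi[j] += v[chain[k + 1]] - v[chain[k]]
    phi /= n_permutations

    base = float(v[mask_index[np.zeros(p, dtype=bool).tobytes()]])
    prediction = float(v[mask_index[np.ones(p, dtype=bool).tobytes()]])
    return Explanation(
        instance_id=instance_id,
        method="shapley",
        attribution=pd.Series(phi, index=names),
        base=base,
        prediction=prediction,
        meta={
            "estimator": "sampled",
            "n_permutations": n_permutations,
            "n_background": background.n,
            "seed": seed,
        },
    )


def global_importance(explanations) -> pd.Series:
    """Mean absolute attribution per feature across explanations.

    The standard global importance score I_i = (1/n) sum_j |phi_i(x^(j))|.
    """
    explanations = list(explanations)
    if not explanations:
        raise ValueError("need at least one explanation")
    names = explanations[0].feature_names
    for e in explanations[1:]:
        if e.feature_names != names and sorted(e.feature_names) != sorted(names):
            raise ValueError("explanations do not share a feature name set")
    mat = pd.concat(
        [e.attribution.reindex(names).abs() for e in explanations], axis=1
    )
    return mat.mean(axis=1)
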
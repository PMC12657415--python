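"""Cohort manipulation protocol for imbalance experiments.

Implements the data-handling steps used when studying how class imbalance in
training data affects models and their explanations: a stratified train/test
split, fixed-total-size training subsets at prescribed minority (case)
proportions, a random-undersampling balanced set, and a balanced test sample.

Conventions (chosen to reproduce the published subset arithmetic exactly):

* the stratified split sends ``floor(test_fraction * class_count)`` rows of
  each class to the test set (so an 80/20 split of 8,412 cases yields
  6,730 train / 1,682 test cases);
* the minority count of a proportion-``q`` subset of total size ``m`` is
  ``round-half-up(q * m)`` (so 1% of 13,460 gives 135 cases, not 134);
* all sampling is without replacement and deterministic under the seed.

The "minority" class is the positive outcome (cases, ``outcome == 1``)
throughout, matching the rare-disease framing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "SubsetSpec",
    "stratified_split",
    "undersample_balanced",
    "make_subset",
    "make_imbalance_subsets",
    "balanced_test_sample",
]


@dataclass(frozen=True)
class SubsetSpec:
    """Requested composition of one fixed-size training subset."""

    minority_proportion: float
    total_size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.minority_proportion <= 0.5):
            raise ValueError("minority_proportion must lie in (0, 0.5]")
        if self.total_size < 2:
            raise ValueError("total_size must be >= 2")
        if self.minority_count < 1:
            raise ValueError("subset would contain no minority rows")

    @property
    def minority_count(self) -> int:
        return _round_half_up(self.minority_proportion * self.total_size)

    @property
    def majority_count(self) -> int:
        return self.total_size - self.minority_count


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _class_positions(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Row *positions* (not index labels) of majority (0) and minority (1)."""
    out = np.asarray(cohort.outcome)
    return np.flatnonzero(out == 0), np.flatnonzero(out == 1)


def _sorted_choice(rng: np.random.Generator, pool: np.ndarray, size: int) -> np.ndarray:
    """Sample without replacement, return positions in original row order."""
    return np.sort(rng.choice(pool, size=size, replace=False))


def stratified_split(
    cohort: Cohort, test_fraction: float, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Split into train/test preserving the class mix.

    Per class, the test set receives ``floor(test_fraction * class_count)``
    rows sampled without replacement; the train set receives the remainder.
    No row appears in both halves.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    neg, pos = _class_positions(cohort)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError(
            f"each class needs >= 2 rows to split (got {len(neg)} controls, {len(pos)} cases)"
        )
    rng = np.random.default_rng(seed)
    test_pos: list[np.ndarray] = []
    for pool in (neg, pos):
        n_test = int(math.floor(test_fraction * len(pool)))
        test_pos.append(_sorted_choice(rng, pool, n_test))
    test_positions = np.sort(np.concatenate(test_pos))
    mask = np.zeros(cohort.n, dtype=bool)
    mask[test_positions] = True
    train = cohort.subset(np.flatnonzero(~mask))
    test = cohort.subset(test_positions)
    return train, test


def undersample_balanced(train: Cohort, seed: int = 0) -> Cohort:
    """Balance by random undersampling: keep every minority (case) row and an
    equal-sized without-replacement sample of majority rows."""
    neg, pos = _class_positions(train)
    if len(pos) < 1:
        raise ValueError("no minority rows to balance around")
    if len(neg) < len(pos):
        raise ValueError(
            f"majority class ({len(neg)}) smaller than minority ({len(pos)}); "
            "undersampling does not apply"
        )
    rng = np.random.default_rng(seed)
    keep_neg = _sorted_choice(rng, neg, len(pos))
    return train.subset(np.sort(np.concatenate([pos, keep_neg])))


def make_subset(
    train: Cohort, n_minority: int, n_majority: int, seed: int = 0
) -> Cohort:
    """Fixed-composition subset with explicit per-class counts.

    This is the primitive behind :func:`make_imbalance_subsets`; it also
    serves conditions whose composition does not follow proportion
    arithmetic (e.g. reproducing a source cohort's original class counts).
    """
    neg, pos = _class_positions(train)
    if n_minority < 1 or n_majority < 1:
        raise ValueError("both class counts must be >= 1")
    if n_minority > len(pos) or n_majority > len(neg):
        raise ValueError(
            f"pool too small: requested {n_minority}/{n_majority} "
            f"(minority/majority) from {len(pos)}/{len(neg)}"
        )
    rng = np.random.default_rng(seed)
    keep_pos = _sorted_choice(rng, pos, n_minority)
    keep_neg = _sorted_choice(rng, neg, n_majority)
    return train.subset(np.sort(np.concatenate([keep_pos, keep_neg])))


def make_imbalance_subsets(
    train: Cohort,
    proportions: list[float] | tuple[float, ...],
    total_size: int,
    seed: int = 0,
) -> list[Cohort]:
    """Training subsets of identical total size at given minority proportions.

    Minority counts follow round-half-up on ``proportion * total_size``; each
    subset is drawn without replacement within each class with its own
    deterministic sub-draw of ``seed``.
    """
    if total_size % 2 != 0:
        raise ValueError("total_size must be even")
    rng = np.random.default_rng(seed)
    subsets = []
    for prop in proportions:
        spec = SubsetSpec(minority_proportion=float(prop), total_size=total_size)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            sub = make_subset(train, spec.minority_count, spec.majority_count, seed=sub_seed)
        except ValueError as err:
            raise ValueError(f"proportion {prop:g}: {err}") from None
        sub.meta["minority_proportion"] = float(prop)
        sub.meta["subset_total_size"] = total_size
        subsets.append(sub)
    return subsets


def balanced_test_sample(test: Cohort, n_per_class: int, seed: int = 0) -> Cohort:
    """Equal-count evaluation sample: ``n_per_class`` rows from each class,
    without replacement.  When ``n_per_class`` equals a class's full count,
    every row of that class is included."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    neg, pos = _class_positions(test)
    for label, pool in (("majority", neg), ("minority", pos)):
        if n_per_class > len(pool):
            raise ValueError(
                f"n_per_class={n_per_class} exceeds {label} class count {len(pool)}"
            )
    rng = np.random.default_rng(seed)
    keep_pos = _sorted_choice(rng, pos, n_per_class)
    keep_neg = _sorted_choice(rng, neg, n_per_class)
    return test.subset(np.sort(np.concatenate([keep_pos, keep_neg])))
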
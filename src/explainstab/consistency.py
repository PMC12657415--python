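"""Top-k rank-agreement statistics for explanation consistency.

Two explanations of the same instance — typically one from a model trained
on balanced data (the reference) and one from a model trained under class
imbalance — are compared through their top-k feature rankings:

* **Jaccard similarity**: |intersection| / |union| of the two top-k feature
  *sets* (order-insensitive);
* **Rank Agreement (union-normalized)**: the number of features that occupy
  the *same rank position* in both rankings, divided by the size of the
  union of the two top-k sets.  Normalizing by the union (rather than by k)
  makes the two metrics directly comparable and guarantees
  rank_agreement <= jaccard on every pair.

Worked example: rankings (a, b, c, d, e) vs (a, f, g, d, e) share {a, d, e},
all three at identical positions; the union has 7 members, so Jaccard and
Rank Agreement are both 3/7.

Features are ranked by descending absolute attribution (global importance is
conventionally mean |attribution|); ties break by ascending feature name so
rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .explainers.base import Explanation

__all__ = [
    "TopKRanking",
    "ConsistencyResult",
    "top_k",
    "jaccard_top_k",
    "rank_agreement",
    "consistency_profile",
    "classwise_consistency",
]


@dataclass(frozen=True)
class TopKRanking:
    """An ordered top-k feature list extracted from one explanation."""

    features: tuple[str, ...]
    k: int
    source: object = None
    all_zero: bool = False  # flags degenerate explanations (every attribution 0)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(set(self.features)) != len(self.features):
            raise ValueError("ranking contains duplicate features")
        if len(self.features) > self.k:
            raise ValueError("ranking longer than k")


def top_k(explanation: Explanation, k: int = 10, signed: bool = False) -> TopKRanking:
    """Extract the top-k ranking of an explanation.

    Ranking score is |attribution| by default (``signed=True`` ranks by the
    raw value instead); ties break by ascending feature name.  When fewer
    than k features carry nonzero attribution, zero-attribution features
    still fill the ranking (alphabetically) so |Top| = min(k, p).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    attr = explanation.attribution
    score = attr if signed else attr.abs()
    ordered = sorted(attr.index, key=lambda name: (-float(score[name]), str(name)))
    return TopKRanking(
        features=tuple(ordered[: min(k, len(ordered))]),
        k=k,
        source=explanation.instance_id,
        all_zero=bool((attr == 0).all()),
    )


def _check_pair(r_a: TopKRanking, r_b: TopKRanking) -> None:
    if r_a.k != r_b.k:
        raise ValueError(f"rankings built with different k ({r_a.k} vs {r_b.k})")


def jaccard_top_k(r_a: TopKRanking, r_b: TopKRanking) -> float:
    """|Top(Ea,k) ∩ Top(Eb,k)| / |Top(Ea,k) ∪ Top(Eb,k)|."""
    _check_pair(r_a, r_b)
    sa, sb = set(r_a.features), set(r_b.features)
    union = sa | sb
    if not union:
        raise ValueError("both rankings are empty")
    return len(sa & sb) / len(union)


def rank_agreement(r_a: TopKRanking, r_b: TopKRanking) -> float:
    """Fraction of the union occupying the same rank position in both rankings."""
    _check_pair(r_a, r_b)
    sa, sb = set(r_a.features), set(r_b.features)
    union = sa | sb
    if not union:
        raise ValueError("both rankings are empty")
    same = sum(
        1 for fa, fb in zip(r_a.features, r_b.features) if fa == fb
    )
    return same / len(union)


@dataclass
class ConsistencyResult:
    """Per-instance and aggregated consistency of two explanation sets."""

    instance_ids: list
    jaccard: np.ndarray
    rank_agreement: np.ndarray
    k: int
    comparison: str = ""
    class_label: str = "all"
    n_degenerate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.jaccard = np.asarray(self.jaccard, dtype=float)
        self.rank_agreement = np.asarray(self.rank_agreement, dtype=float)
        if len(self.jaccard) != len(self.instance_ids) or len(self.rank_agreement) != len(
            self.instance_ids
        ):
            raise ValueError("per-instance arrays misaligned with instance ids")

    @property
    def n(self) -> int:
        return len(self.instance_ids)

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def se(self, metric: str) -> float:
        """Standard error: sample standard deviation / sqrt(n)."""
        v = self._values(metric)
        if len(v) < 2:
            return float("nan")
        return float(v.std(ddof=1) / np.sqrt(len(v)))

    def _values(self, metric: str) -> np.ndarray:
        try:
            return {"jaccard": self.jaccard, "rank_agreement": self.rank_agreement}[metric]
        except KeyError:
            raise KeyError(f"unknown metric {metric!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("jaccard", "rank_agreement"):
            for iid, val in zip(self.instance_ids, self._values(metric)):
                rows.append(
                    {
                        "comparison": self.comparison,
                        "class": self.class_label,
                        "metric": metric,
                        "instance_id": iid,
                        "value": val,
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": self.comparison,
                "class": self.class_label,
                "metric": metric,
                "mean": self.mean(metric),
                "se": self.se(metric),
                "n": self.n,
                "k": self.k,
            }
            for metric in ("jaccard", "rank_agreement")
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def consistency_profile(
    reference_explanations: Sequence[Explanation],
    test_explanations: Sequence[Explanation],
    k: int = 10,
    comparison: str = "",
    class_label: str = "all",
    signed: bool = False,
) -> ConsistencyResult:
    """Instance-matched Jaccard / Rank Agreement between two explanation sets.

    The two lists must cover the same instance identifiers; for each
    instance the reference and test explanations are reduced to top-k
    rankings and compared.  Means and standard errors aggregate over
    instances.
    """
    ref = {e.instance_id: e for e in reference_explanations}
    tst = {e.instance_id: e for e in test_explanations}
    if len(ref) != len(reference_explanations) or len(tst) != len(test_explanations):
        raise ValueError("duplicate instance ids within an explanation list")
    orphans = set(ref) ^ set(tst)
    if orphans:
        raise ValueError(f"instance ids not present in both lists: {sorted(map(str, orphans))}")
    if len(ref) < 2:
        raise ValueError("need at least 2 matched instances")

    ids = list(ref)
    jac = np.empty(len(ids))
    ra = np.empty(len(ids))
    n_degenerate = 0
    for i, iid in enumerate(ids):
        r_ref = top_k(ref[iid], k, signed=signed)
        r_tst = top_k(tst[iid], k, signed=signed)
        n_degenerate += int(r_ref.all_zero) + int(r_tst.all_zero)
        jac[i] = jaccard_top_k(r_ref, r_tst)
        ra[i] = rank_agreement(r_ref, r_tst)
    return ConsistencyResult(
        instance_ids=ids,
        jaccard=jac,
        rank_agreement=ra,
        k=k,
        comparison=comparison,
        class_label=class_label,
        n_degenerate=n_degenerate,
    )


def classwise_consistency(
    reference_explanations: Sequence[Explanation],
    test_explanations: Sequence[Explanation],
    labels: dict,
    k: int = 10,
    n_per_class: int = 100,
    seed: int = 0,
    comparison: str = "",
    signed: bool = False,
) -> tuple[ConsistencyResult, ConsistencyResult]:
    """Consistency evaluated separately for minority (1) and majority (0)
    instances, on a seeded selection of ``n_per_class`` instances per class.

    ``labels`` maps instance id -> outcome class.  Returns the (minority,
    majority) results.
    """
    ref_ids = {e.instance_id for e in reference_explanations}
    by_class: dict[int, list] = {0: [], 1: []}
    for iid in ref_ids:
        if iid not in labels:
            raise ValueError(f"no class label for instance {iid!r}")
        by_class[int(labels[iid])].append(iid)
    for cls in (0, 1):
        if len(by_class[cls]) < n_per_class:
            raise ValueError(
                f"class {cls} has only {len(by_class[cls])} explained instances "
                f"(need {n_per_class}); class counts: "
                f"{{0: {len(by_class[0])}, 1: {len(by_class[1])}}}"
            )
    rng = np.random.default_rng(seed)
    results = {}
    for cls, label in ((1, "minority"), (0, "majority")):
        pool = sorted(by_class[cls], key=str)
        chosen = set(rng.choice(np.array(pool, dtype=object), size=n_per_class, replace=False))
        results[label] = consistency_profile(
            [e for e in reference_explanations if e.instance_id in chosen],
            [e for e in test_explanations if e.instance_id in chosen],
            k=k,
            comparison=comparison,
            class_label=label,
            signed=signed,
        )
    return results["minority"], results["majority"]
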
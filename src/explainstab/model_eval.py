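"""Model performance evaluation and nonparametric comparison tests.

Covers the evaluation machinery of the imbalance study: ROC-AUC, the
Youden-J optimal operating point (sensitivity + specificity − 1 maximized
over observed score thresholds), stratified bootstrap distributions of
performance metrics, the Mann-Whitney U test for comparing two performance
distributions, and the Wilcoxon signed-rank test for paired per-instance
consistency values.

Threshold convention: the classification rule is ``score >= t -> positive``;
candidate thresholds are the distinct observed scores; Youden ties resolve
to the lowest threshold (favoring sensitivity, the clinically conservative
choice for a rare disease).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "PerformanceSummary",
    "TestResult",
    "roc_auc",
    "youden_threshold",
    "sensitivity_specificity",
    "bootstrap_metric",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
]


@dataclass
class PerformanceSummary:
    """Operating characteristics of one trained model on one test set."""

    model: str
    condition: str
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    n_test: int
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "condition": self.condition,
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_test": self.n_test,
        }


@dataclass
class TestResult:
    """Outcome of a two-sided nonparametric test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...] | int
    alternative: str = "two-sided"
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def sensitivity_specificity(scores, labels, threshold: float) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    pos = labels == 1
    sens = float(pred[pos].mean())
    spec = float((~pred[~pos]).mean())
    return sens, spec


def youden_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Maximize J(t) = sensitivity(t) + specificity(t) − 1 over observed scores.

    Returns ``(threshold, J, sensitivity, specificity)``.  Ties on J resolve
    to the lowest candidate threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    cands = np.unique(scores)  # ascending
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    # sens(t) = P(pos score >= t); spec(t) = P(neg score < t)
    # integer ratios keep J bit-identical to a direct count-based scan
    sens = (n_pos - np.searchsorted(pos_sorted, cands, side="left")) / n_pos
    spec = np.searchsorted(neg_sorted, cands, side="left") / n_neg
    J = sens + spec - 1.0
    best = int(np.argmax(J))  # argmax returns the first (lowest) maximizer
    return float(cands[best]), float(J[best]), float(sens[best]), float(spec[best])


_METRICS = ("auc", "sensitivity", "specificity", "youden_j")


def _metric_value(scores: np.ndarray, labels: np.ndarray, metric: str) -> float:
    if metric == "auc":
        return roc_auc(scores, labels)
    t, j, sens, spec = youden_threshold(scores, labels)
    return {"sensitivity": sens, "specificity": spec, "youden_j": j}[metric]


def bootstrap_metric(
    scores,
    labels,
    metric: str = "auc",
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap distribution of a performance metric on a test set.

    Resampling is with replacement *within each class* (stratified), so
    every replicate retains both classes.  Sensitivity and specificity are
    recomputed at each replicate's own Youden threshold.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    out = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        out[b] = _metric_value(scores[take], labels[take], metric)
    return out


_EXACT_MWU_LIMIT = 400  # exact enumeration when n_a * n_b is at most this and no ties


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when the samples are small (``n_a * n_b <= 400``)
    and tie-free; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and len(a) * len(b) <= _EXACT_MWU_LIMIT
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(len(a), len(b)),
        note=method,
    )


_EXACT_WILCOXON_LIMIT = 12


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are handled by the Pratt method (included in the
    ranking, then dropped from the signed sums); tied |d| receive midranks.
    Exact enumeration applies for n <= 12 when there are no zeros and no
    ties; otherwise the normal approximation with continuity correction.
    All differences zero is degenerate: p = 1 with a flag, since the paired
    samples are indistinguishable.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return TestResult(
            test="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n=len(a),
            degenerate=True,
            note="all paired differences are zero",
        )
    nz = d[d != 0]
    no_zeros = len(nz) == len(d)
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    if no_zeros and no_ties and len(d) <= _EXACT_WILCOXON_LIMIT:
        res = sps.wilcoxon(a, b, alternative="two-sided", method="exact")
        note = "exact"
    else:
        res = sps.wilcoxon(
            a,
            b,
            alternative="two-sided",
            method="approx",
            zero_method="pratt",
            correction=True,
        )
        note = "asymptotic-pratt"
    return TestResult(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=len(a),
        note=note,
    )
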
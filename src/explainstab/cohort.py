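"""Synthetic tabular cohort generation for binary clinical outcomes.

This module simulates electronic-health-record-style cohorts with a mix of
continuous, categorical and binary features and a binary outcome drawn from
an additive logistic risk model.  The motivating setting is rare-disease risk
prediction (e.g. lung-cancer incidence in primary care, prevalence well below
1%), where the real cohorts are access-restricted: the generator reproduces
the *statistical shape* of such data — one continuous age variable, a
multi-level smoking status, a couple of dozen comorbidity/symptom flags, and
a controllable minority prevalence — so that model training, undersampling
protocols and explanation methods can be exercised end to end.

The outcome model is logistic-additive on purpose: it admits closed-form
expectations that downstream explanation code can be verified against.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "Cohort",
    "risk_probability",
    "risk_probabilities",
    "calibrate_intercept",
    "generate_cohort",
    "default_lung_cancer_spec",
    "encode_frame",
    "encoded_columns",
]

_KINDS = ("continuous", "categorical", "binary")


@dataclass(frozen=True)
class FeatureSpec:
    """Distribution and risk-effect description of one cohort feature.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    kind : {"continuous", "categorical", "binary"}
    levels : sequence of str, categorical only
        Ordered category labels; the first level is the reference level of
        the one-hot encoding and its log-odds effect is fixed at 0.
    loc, scale, lower, upper : float, continuous only
        Parameters of a (possibly truncated) normal sampling distribution.
    probs : sequence of float, categorical only
        Level probabilities; must sum to 1.  May be ``None`` for schemas
        loaded from disk, in which case the feature cannot be re-sampled.
    rate : float, binary only
        Bernoulli success rate.
    effect : float or sequence of float
        Log-odds contribution(s) to the outcome model: a single slope for
        continuous/binary features, one value per level (first fixed at 0)
        for categorical features.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    loc: float = 0.0
    scale: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf
    probs: tuple[float, ...] | None = None
    rate: float = 0.5
    effect: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        eff = self.effect
        if np.isscalar(eff):
            eff = (float(eff),)
        object.__setattr__(self, "effect", tuple(float(e) for e in eff))
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"categorical feature {self.name!r} needs >= 2 levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in feature {self.name!r}")
            if self.probs is not None:
                probs = tuple(float(p) for p in self.probs)
                if len(probs) != len(self.levels):
                    raise ValueError(f"{self.name!r}: len(probs) != len(levels)")
                if any(p < 0 or p > 1 for p in probs):
                    raise ValueError(f"{self.name!r}: probabilities must lie in [0, 1]")
                if abs(sum(probs) - 1.0) > 1e-12:
                    raise ValueError(f"{self.name!r}: probabilities must sum to 1")
                object.__setattr__(self, "probs", probs)
            if len(self.effect) != len(self.levels):
                raise ValueError(
                    f"{self.name!r}: need one effect per level "
                    f"({len(self.levels)}), got {len(self.effect)}"
                )
            if self.effect[0] != 0.0:
                raise ValueError(f"{self.name!r}: first-level effect must be 0 (reference)")
        else:
            if self.levels is not None:
                raise ValueError(f"{self.name!r}: levels only apply to categorical features")
            if len(self.effect) != 1:
                raise ValueError(f"{self.name!r}: exactly one effect coefficient expected")
            if self.kind == "continuous" and not self.scale > 0:
                raise ValueError(f"{self.name!r}: continuous scale must be > 0")
            if self.kind == "binary" and not 0.0 <= self.rate <= 1.0:
                raise ValueError(f"{self.name!r}: Bernoulli rate must lie in [0, 1]")

    @property
    def n_levels(self) -> int:
        return len(self.levels) if self.levels else 0


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort: features, risk model, size.

    ``intercept=None`` requests automatic calibration (at generation time)
    so that the population mean risk matches ``target_prevalence``.
    """

    features: tuple[FeatureSpec, ...]
    target_prevalence: float = 0.5
    intercept: float | None = None
    n: int = 1000
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in CohortSpec")
        if self.outcome_name in names:
            raise ValueError("outcome column name collides with a feature name")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    def with_n(self, n: int) -> "CohortSpec":
        return replace(self, n=n)

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def encoded_columns(feature: FeatureSpec) -> list[str]:
    """Column names a feature contributes to the numeric design matrix."""
    if feature.kind == "categorical":
        return [f"{feature.name}={lvl}" for lvl in feature.levels[1:]]
    return [feature.name]


def encode_frame(frame: pd.DataFrame, features: Sequence[FeatureSpec]) -> pd.DataFrame:
    """One-hot encode a raw feature table against the declared schema.

    Continuous and binary columns pass through as floats; each categorical
    feature becomes ``n_levels - 1`` indicator columns relative to its first
    (reference) level.  All model adapters and explainers share this design
    matrix, so every consumer of a cohort sees the same numeric view.
    """
    cols: dict[str, np.ndarray] = {}
    for f in features:
        if f.name not in frame.columns:
            raise KeyError(f"feature {f.name!r} missing from frame")
        col = frame[f.name]
        if f.kind == "categorical":
            values = col.to_numpy(dtype=object)
            known = set(f.levels)
            bad = {v for v in values if v not in known}
            if bad:
                raise ValueError(
                    f"feature {f.name!r}: unknown level(s) {sorted(map(str, bad))!r}"
                )
            for lvl in f.levels[1:]:
                cols[f"{f.name}={lvl}"] = (values == lvl).astype(float)
        else:
            cols[f.name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=frame.index)


@dataclass
class Cohort:
    """A feature table plus binary outcome and the schema describing it.

    Row identity is the frame's (positional) index, carried unchanged through
    splitting and subsetting so that partition checks and instance matching
    remain possible downstream.
    """

    frame: pd.DataFrame
    outcome: np.ndarray
    features: tuple[FeatureSpec, ...]
    outcome_name: str = "outcome"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        if len(self.frame) == 0:
            raise ValueError("cohort must contain at least one row")
        if len(self.outcome) != len(self.frame):
            raise ValueError("outcome length does not match frame")
        if not np.isin(self.outcome, (0, 1)).all():
            raise ValueError("outcome must contain only 0/1")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate column names in cohort frame")
        for f in self.features:
            if f.name not in self.frame.columns:
                raise ValueError(f"schema feature {f.name!r} missing from frame")
            col = self.frame[f.name]
            if f.kind == "categorical":
                bad = set(col.unique()) - set(f.levels)
                if bad:
                    raise ValueError(
                        f"feature {f.name!r} contains undeclared level(s) {sorted(map(str, bad))!r}"
                    )
            elif col.isna().any():
                raise ValueError(f"feature {f.name!r} contains missing values")

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def class_counts(self) -> tuple[int, int]:
        """(majority=0 count, minority=1 count) — counts of controls and cases."""
        n1 = int(self.outcome.sum())
        return len(self.outcome) - n1, n1

    def feature(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subset(self, positions: Iterable[int]) -> "Cohort":
        """New cohort from integer row *positions*, keeping original row ids."""
        pos = np.asarray(list(positions), dtype=int)
        return Cohort(
            frame=self.frame.iloc[pos],
            outcome=self.outcome[pos],
            features=self.features,
            outcome_name=self.outcome_name,
            seed=self.seed,
            meta=dict(self.meta),
        )

    def encode(self) -> pd.DataFrame:
        return encode_frame(self.frame, self.features)

    @property
    def encoded_column_names(self) -> list[str]:
        out: list[str] = []
        for f in self.features:
            out.extend(encoded_columns(f))
        return out

    # -- persistence ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the cohort as CSV plus a ``.schema.json`` sidecar.

        The sidecar records feature kinds and level sets, the outcome column
        name and the generation seed, so a read round-trip is lossless for
        both values and metadata.
        """
        path = Path(path)
        table = self.frame.copy()
        table[self.outcome_name] = self.outcome
        table.to_csv(path, index_label="row_id")
        schema = {
            "outcome": self.outcome_name,
            "seed": self.seed,
            "meta": self.meta,
            "features": [
                {"name": f.name, "kind": f.kind, "levels": list(f.levels) if f.levels else None}
                for f in self.features
            ],
        }
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        sidecar.write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        schema = json.loads(sidecar.read_text())
        feats = []
        dtypes: dict[str, object] = {}
        for f in schema["features"]:
            if f["kind"] == "categorical":
                feats.append(
                    FeatureSpec(
                        name=f["name"],
                        kind="categorical",
                        levels=tuple(f["levels"]),
                        effect=(0.0,) * len(f["levels"]),
                    )
                )
                dtypes[f["name"]] = str
            else:
                feats.append(FeatureSpec(name=f["name"], kind=f["kind"]))
                dtypes[f["name"]] = float if f["kind"] == "continuous" else int
        table = pd.read_csv(path, index_col="row_id", dtype=dtypes)
        table.index.name = None
        outcome = table.pop(schema["outcome"]).to_numpy()
        return cls(
            frame=table,
            outcome=outcome,
            features=tuple(feats),
            outcome_name=schema["outcome"],
            seed=schema.get("seed"),
            meta=schema.get("meta") or {},
        )


# -- risk model -----------------------------------------------------------

def _linear_predictor(frame: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    eta = np.zeros(len(frame), dtype=float)
    for f in spec.features:
        col = frame[f.name]
        if f.kind == "categorical":
            lut = {lvl: eff for lvl, eff in zip(f.levels, f.effect)}
            vals = col.to_numpy(dtype=object)
            contrib = np.empty(len(vals), dtype=float)
            for i, v in enumerate(vals):
                try:
                    contrib[i] = lut[v]
                except KeyError:
                    raise ValueError(
                        f"feature {f.name!r}: unknown category level {v!r}"
                    ) from None
            eta += contrib
        else:
            eta += f.effect[0] * col.to_numpy(dtype=float)
    return eta


def risk_probabilities(frame: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Vector of logistic outcome probabilities for every row of ``frame``."""
    if spec.intercept is None:
        raise ValueError("spec intercept is unset; calibrate it first")
    return expit(spec.intercept + _linear_predictor(frame, spec))


def risk_probability(feature_row: Mapping | pd.Series, spec: CohortSpec) -> float:
    """Outcome probability ``logistic(intercept + sum(effects * x))`` for one row."""
    row = pd.DataFrame([dict(feature_row)])
    return float(risk_probabilities(row, spec)[0])


def _sample_features(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for f in spec.features:
        if f.kind == "continuous":
            if f.upper == f.lower:
                if f.effect[0] != 0.0:
                    warnings.warn(
                        f"feature {f.name!r} is degenerate (zero variance) but has a "
                        "nonzero effect; proceeding",
                        stacklevel=2,
                    )
                cols[f.name] = np.full(n, float(f.lower))
            else:
                a = (f.lower - f.loc) / f.scale
                b = (f.upper - f.loc) / f.scale
                cols[f.name] = stats.truncnorm.rvs(
                    a, b, loc=f.loc, scale=f.scale, size=n, random_state=rng
                )
        elif f.kind == "categorical":
            if f.probs is None:
                raise ValueError(f"feature {f.name!r} has no level probabilities to sample")
            cols[f.name] = rng.choice(np.array(f.levels, dtype=object), size=n, p=f.probs)
        else:
            cols[f.name] = rng.binomial(1, f.rate, size=n)
    return pd.DataFrame(cols)


def calibrate_intercept(
    spec: CohortSpec,
    tolerance: float = 1e-4,
    seed: int = 0,
    n_sample: int = 500_000,
    bracket: tuple[float, float] = (-40.0, 40.0),
) -> float:
    """Intercept whose Monte-Carlo mean risk matches ``spec.target_prevalence``.

    The mean of ``logistic(c + eta)`` over a fixed feature sample is strictly
    increasing in the intercept ``c``, so a bracketing root search converges;
    the result is checked against ``tolerance`` on the prevalence scale.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    rng = np.random.default_rng(seed)
    frame = _sample_features(spec, n_sample, rng)
    eta = _linear_predictor(frame, spec)

    def gap(c: float) -> float:
        return float(expit(c + eta).mean() - spec.target_prevalence)

    lo, hi = bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"intercept calibration failed: target {spec.target_prevalence} not "
            f"bracketed by intercepts in [{lo}, {hi}]"
        )
    c = optimize.brentq(gap, lo, hi, xtol=1e-10, maxiter=200)
    if abs(gap(c)) > tolerance:
        raise RuntimeError(
            f"intercept calibration did not reach tolerance {tolerance} "
            f"(bracket [{lo}, {hi}], residual {gap(c):.3g})"
        )
    return float(c)


def generate_cohort(spec: CohortSpec, seed: int = 0) -> Cohort:
    """Sample a cohort: features from their declared distributions, outcome
    Bernoulli at the logistic risk of each row.

    Identical ``(spec, seed)`` pairs produce bit-identical cohorts.  When the
    spec's intercept is unset it is calibrated first (deterministically from
    ``seed``) to hit ``target_prevalence``.
    """
    if spec.intercept is None:
        intercept = calibrate_intercept(spec, seed=_calibration_seed(seed))
        spec = replace(spec, intercept=intercept)
    rng = np.random.default_rng(seed)
    frame = _sample_features(spec, spec.n, rng)
    p = risk_probabilities(frame, spec)
    outcome = rng.binomial(1, p)
    return Cohort(
        frame=frame,
        outcome=outcome,
        features=spec.features,
        outcome_name=spec.outcome_name,
        seed=seed,
        meta={
            "source": "synthetic",
            "intercept": spec.intercept,
            "target_prevalence": spec.target_prevalence,
        },
    )


def _calibration_seed(seed: int) -> int:
    from ._seeding import derive_seed

    return derive_seed(seed, "calibrate_intercept")


# -- default cohort -------------------------------------------------------

SMOKING_LEVELS: tuple[str, ...] = (
    "Ex Unknown",
    "Ex Light",
    "Ex Moderate",
    "Ex Heavy",
    "Current Unknown",
    "Current Light",
    "Current Moderate",
    "Current Heavy",
    "Missing",
)

# (name, Bernoulli rate, log-odds effect) for the comorbidity/symptom flags.
# Rates and effects are illustrative (no public reference distribution exists
# for this kind of cohort); effects are largest for the classic red-flag
# symptoms and established risk factors.
_BINARY_FLAGS: tuple[tuple[str, float, float], ...] = (
    ("bronchiectasis", 0.010, 0.30),
    ("cerebrovascular_disease", 0.040, 0.10),
    ("chronic_kidney_disease", 0.050, 0.10),
    ("copd_emphysema", 0.060, 0.80),
    ("diabetes_end_stage", 0.010, 0.20),
    ("diabetes_no_end_stage", 0.080, 0.10),
    ("family_history_cancer", 0.150, 0.20),
    ("family_history_lung_cancer", 0.030, 0.70),
    ("idiopathic_fibrosis", 0.005, 0.50),
    ("lower_respiratory_tract_infection", 0.120, 0.40),
    ("bmi_abnormal", 0.300, 0.10),
    ("peptic_ulcer", 0.030, 0.05),
    ("alcohol_misuse", 0.080, 0.15),
    ("peripheral_vascular_disease", 0.030, 0.20),
    ("radiotherapy_history", 0.010, 0.40),
    ("breast_cancer_history", 0.030, 0.20),
    ("bladder_cancer_history", 0.008, 0.30),
    ("head_neck_cancer_history", 0.005, 0.50),
    ("thyroid_cancer_history", 0.005, 0.10),
    ("dyspnoea", 0.100, 0.50),
    ("haemoptysis", 0.005, 1.50),
    ("cough", 0.200, 0.60),
    ("sputum_production", 0.080, 0.40),
    ("back_pain", 0.150, 0.10),
    ("blood_test_performed", 0.400, 0.20),
    ("weight_loss", 0.040, 0.90),
)

# Smoking effects rise with intensity; current smokers above ex-smokers.
_SMOKING_EFFECTS = (0.0, 0.15, 0.35, 0.55, 0.45, 0.60, 0.85, 1.20, 0.10)
_SMOKING_PROBS = (0.10, 0.09, 0.07, 0.05, 0.04, 0.06, 0.05, 0.04, 0.50)


def default_lung_cancer_spec(n: int = 100_000) -> CohortSpec:
    """A lung-cancer-style rare-outcome cohort specification.

    One continuous feature (age, truncated normal on the screening-age range
    30–90), one nine-level smoking status/intensity categorical, and 26
    binary comorbidity/symptom flags; target minority prevalence 0.6%.  The
    intercept is left unset and is calibrated at generation time.
    """
    features = [
        FeatureSpec(
            name="age",
            kind="continuous",
            loc=62.0,
            scale=12.0,
            lower=30.0,
            upper=90.0,
            effect=(0.045,),
        ),
        FeatureSpec(
            name="smoking_status",
            kind="categorical",
            levels=SMOKING_LEVELS,
            probs=_SMOKING_PROBS,
            effect=_SMOKING_EFFECTS,
        ),
    ]
    for name, rate, eff in _BINARY_FLAGS:
        features.append(FeatureSpec(name=name, kind="binary", rate=rate, effect=(eff,)))
    return CohortSpec(
        features=tuple(features),
        target_prevalence=0.006,
        intercept=None,
        n=n,
    )
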
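"""Config-driven orchestration of the imbalance/explanation-consistency sweep.

One call to :func:`run_sweep` executes the whole protocol:

1. generate (or load) a cohort and split it with stratification;
2. build fixed-size training subsets at the configured minority proportions,
   the 50% subset being the balanced reference condition;
3. train each configured model on each subset and evaluate it on a balanced
   test sample (AUC, Youden operating point), with stratified bootstrap
   distributions compared to the balanced reference by Mann-Whitney U;
4. explain the SAME seeded set of test instances under every condition with
   LIME and Shapley values, and compute Jaccard / Rank Agreement consistency
   of each condition's explanations against the balanced reference, overall
   and per outcome class, with Wilcoxon signed-rank tests;
5. emit partial dependence profiles for configured features under the
   balanced and the most imbalanced conditions.

Every stage draws its randomness from a sub-seed derived from the master
seed and the stage name, so results are fully deterministic under a fixed
config and insensitive to stage insertion elsewhere in the pipeline.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .cohort import Cohort, CohortSpec, default_lung_cancer_spec, generate_cohort
from .cohort_ops import (
    balanced_test_sample,
    make_imbalance_subsets,
    stratified_split,
    undersample_balanced,
)
from .consistency import ConsistencyResult, classwise_consistency, consistency_profile
from .explainers import (
    EXACT_FEATURE_CAP,
    LimeConfig,
    build_model,
    lime_explain,
    model_adapter_registry,
    pdp_categorical,
    pdp_continuous,
    quantile_grid,
    shapley_exact,
    shapley_sampled,
)
from .model_eval import (
    PerformanceSummary,
    bootstrap_metric,
    mann_whitney_u,
    roc_auc,
    wilcoxon_signed_rank,
    youden_threshold,
)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "run_sweep",
    "shrinkage_study",
    "consistency_trend",
    "model_adapter_registry",
]

logger = logging.getLogger("explainstab")

REFERENCE_PROPORTION = 0.5


@dataclass
class ExperimentConfig:
    """Everything a sweep needs; defaults give a desk-scale run.

    The default scale (cohort of 40,000, subsets of 2,000 rows, 50 explained
    instances, sampled Shapley values) keeps a full sweep to a few minutes
    on one CPU while preserving the protocol's structure; every knob scales
    up to larger studies unchanged.
    """

    cohort_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    cohort_n: int = 40_000
    # Prevalence of the default synthetic sweep cohort.  Scaled up from the
    # rare-disease 0.6% so that a 40,000-row cohort can supply a balanced
    # subset of `subset_total` rows; the *subset* proportions, not the pool
    # prevalence, define the imbalance conditions under study.
    cohort_prevalence: float = 0.04
    test_fraction: float = 0.2
    proportions: tuple[float, ...] = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01)
    subset_total: int | None = 2_000  # None: twice the training minority pool
    include_original: bool = False  # add a condition trained on the full training pool
    models: tuple[str, ...] = ("logistic",)
    k: int = 10
    n_explain: int = 50
    n_per_class: int = 0  # 0 disables the class-wise analysis
    test_n_per_class: int | None = None  # None: all minority test rows
    lime_n_perturbations: int = 400
    lime_ridge: float = 1e-6
    shap_mode: str = "auto"  # auto | exact | sampled
    shap_n_permutations: int = 16
    background_cap: int = 100
    pdp_features: tuple[str, ...] = ("age", "smoking_status")
    pdp_grid_points: int = 15
    n_boot: int = 100
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.proportions = tuple(float(p) for p in self.proportions)
        self.models = tuple(self.models)
        self.pdp_features = tuple(self.pdp_features)
        for p in self.proportions:
            if not (0.0 < p <= 0.5):
                raise ValueError(f"proportion {p} outside (0, 0.5]")
        if REFERENCE_PROPORTION not in self.proportions:
            self.proportions = (REFERENCE_PROPORTION,) + self.proportions
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.shap_mode not in ("auto", "exact", "sampled"):
            raise ValueError("shap_mode must be auto, exact or sampled")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.cohort_spec is not None:
            d["cohort_spec"] = "custom"
        return d


def condition_label(proportion: float | None) -> str:
    if proportion is None:
        return "original"
    if proportion == REFERENCE_PROPORTION:
        return "balanced"
    return f"{100 * proportion:g}%"


@dataclass
class SweepResult:
    """In-memory result bundle of one sweep; mirrors the on-disk CSV layout."""

    performance: pd.DataFrame
    performance_tests: pd.DataFrame
    consistency: pd.DataFrame  # per-instance long format
    consistency_summary: pd.DataFrame
    consistency_tests: pd.DataFrame
    pdp: pd.DataFrame
    manifest: dict
    results: dict = field(default_factory=dict)  # (model, method, condition, class) -> ConsistencyResult

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(outdir / "performance.csv", index=False)
        self.performance_tests.to_csv(outdir / "performance_tests.csv", index=False)
        self.consistency.to_csv(outdir / "consistency_instances.csv", index=False)
        self.consistency_summary.to_csv(outdir / "consistency_summary.csv", index=False)
        self.consistency_tests.to_csv(outdir / "consistency_tests.csv", index=False)
        self.pdp.to_csv(outdir / "pdp.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _load_cohort(config: ExperimentConfig) -> Cohort:
    if config.cohort_csv is not None:
        return Cohort.from_csv(config.cohort_csv)
    if config.cohort_spec is not None:
        spec = config.cohort_spec
    else:
        from dataclasses import replace

        spec = replace(
            default_lung_cancer_spec(), target_prevalence=config.cohort_prevalence
        )
    spec = spec.with_n(config.cohort_n)
    return generate_cohort(spec, seed=derive_seed(config.seed, "cohort"))


def _explain_set(
    model,
    instances: pd.DataFrame,
    background: Cohort,
    config: ExperimentConfig,
    stage: str,
) -> dict[str, list]:
    """LIME and Shapley explanations for every row of ``instances``."""
    p = len(background.features)
    use_exact = config.shap_mode == "exact" or (
        config.shap_mode == "auto" and p <= EXACT_FEATURE_CAP
    )
    lime_cfg = LimeConfig(
        n_perturbations=config.lime_n_perturbations,
        ridge_penalty=config.lime_ridge,
        seed=derive_seed(config.seed, f"{stage}:lime"),
    )
    shap_seed = derive_seed(config.seed, f"{stage}:shap")
    lime_out, shap_out = [], []
    for iid, row in instances.iterrows():
        lime_out.append(
            lime_explain(model, row, background, lime_cfg, instance_id=iid)
        )
        if use_exact:
            shap_out.append(
                shapley_exact(model, row, background, instance_id=iid)
            )
        else:
            shap_out.append(
                shapley_sampled(
                    model,
                    row,
                    background,
                    n_permutations=config.shap_n_permutations,
                    seed=shap_seed,
                    instance_id=iid,
                )
            )
    return {"lime": lime_out, "shapley": shap_out}


def run_sweep(config: ExperimentConfig) -> SweepResult:
    """Execute the full experiment described by ``config``.

    Returns the result bundle; additionally writes CSV outputs and a JSON
    manifest when ``config.outdir`` is set.  Deterministic under
    ``(config, seed)``.
    """
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0, 3)
        logger.info("stage %-24s t=%.1fs", stage, stage_times[stage])

    cohort = _load_cohort(config)
    tick("cohort")

    train, test = stratified_split(
        cohort, config.test_fraction, seed=derive_seed(config.seed, "split")
    )
    n_test_minority = int(test.outcome.sum())
    n_eval = config.test_n_per_class or n_test_minority
    eval_set = balanced_test_sample(test, n_eval, seed=derive_seed(config.seed, "test_sample"))
    tick("split")

    subset_total = config.subset_total
    if subset_total is None:
        subset_total = 2 * int(train.outcome.sum())
    subsets = make_imbalance_subsets(
        train,
        config.proportions,
        subset_total,
        seed=derive_seed(config.seed, "subsets"),
    )
    conditions: list[tuple[str, float | None, Cohort]] = [
        (condition_label(p), p, s) for p, s in zip(config.proportions, subsets)
    ]
    if config.include_original:
        conditions.append(("original", None, train))
    tick("subsets")

    # instance selection: shared across all models and conditions
    rng = np.random.default_rng(derive_seed(config.seed, "instances"))
    ids = np.array(eval_set.frame.index)
    n_explain = min(config.n_explain, len(ids))
    chosen = np.sort(rng.choice(ids, size=n_explain, replace=False))
    labels = dict(zip(eval_set.frame.index, eval_set.outcome))
    classwise_ids: dict[int, np.ndarray] = {}
    if config.n_per_class > 0:
        cw_rng = np.random.default_rng(derive_seed(config.seed, "classwise_instances"))
        for cls in (0, 1):
            pool = np.array([i for i in ids if labels[i] == cls])
            if len(pool) < config.n_per_class:
                raise ValueError(
                    f"class {cls} has {len(pool)} eval rows; "
                    f"n_per_class={config.n_per_class} unavailable"
                )
            classwise_ids[cls] = np.sort(
                cw_rng.choice(pool, size=config.n_per_class, replace=False)
            )
    explain_ids = set(chosen)
    for arr in classwise_ids.values():
        explain_ids |= set(arr)
    explain_frame = eval_set.frame.loc[sorted(explain_ids)]

    perf_rows, perf_test_rows = [], []
    cons_frames, cons_summary_frames, cons_test_rows = [], [], []
    pdp_frames = []
    results: dict = {}
    manifest_conditions = []
    registry = model_adapter_registry()
    for name in config.models:
        if name not in registry:
            raise KeyError(f"unknown model {name!r}; available: {sorted(registry)}")

    most_imbalanced = (
        "original" if config.include_original else condition_label(min(config.proportions))
    )

    for model_name in config.models:
        explanations: dict[str, dict[str, list]] = {}
        boots: dict[str, dict[str, np.ndarray]] = {}
        for label, prop, subset in conditions:
            stage = f"model:{model_name}:{label}"
            adapter = build_model(model_name, seed=derive_seed(config.seed, stage))
            adapter.fit(subset)

            scores = adapter.predict(eval_set.frame)
            thr, j, sens, spec = youden_threshold(scores, eval_set.outcome)
            summary = PerformanceSummary(
                model=model_name,
                condition=label,
                auc=roc_auc(scores, eval_set.outcome),
                youden_threshold=thr,
                sensitivity=sens,
                specificity=spec,
                n_test=eval_set.n,
                meta={"minority_proportion": prop, "youden_j": j},
            )
            row = summary.as_dict()
            row["minority_proportion"] = prop
            row["youden_j"] = j
            perf_rows.append(row)
            boots[label] = {
                metric: bootstrap_metric(
                    scores,
                    eval_set.outcome,
                    metric,
                    n_boot=config.n_boot,
                    seed=derive_seed(config.seed, f"{stage}:boot:{metric}"),
                )
                for metric in ("auc", "sensitivity", "specificity")
            }

            bg_rng = np.random.default_rng(derive_seed(config.seed, f"{stage}:background"))
            if subset.n > config.background_cap:
                background = subset.subset(
                    np.sort(bg_rng.choice(subset.n, size=config.background_cap, replace=False))
                )
            else:
                background = subset
            explanations[label] = _explain_set(
                adapter, explain_frame, background, config, stage
            )

            counts = subset.class_counts()
            manifest_conditions.append(
                {
                    "model": model_name,
                    "condition": label,
                    "minority_proportion": prop,
                    "n_minority": counts[1],
                    "n_majority": counts[0],
                }
            )
            tick(stage)

        ref_label = "balanced"
        for label, prop, subset in conditions:
            # bootstrap performance comparison vs the balanced reference
            if label != ref_label:
                for metric in ("auc", "sensitivity", "specificity"):
                    res = mann_whitney_u(boots[label][metric], boots[ref_label][metric])
                    perf_test_rows.append(
                        {
                            "model": model_name,
                            "condition": label,
                            "metric": metric,
                            "test": res.test,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "n_boot": config.n_boot,
                            # bootstrap replicates are resamples, not independent
                            # draws; the comparison follows the study protocol
                            "note": "bootstrap-replicate comparison",
                        }
                    )
            for method in ("lime", "shapley"):
                ref_expl = [
                    e for e in explanations[ref_label][method] if e.instance_id in set(chosen)
                ]
                tst_expl = [
                    e for e in explanations[label][method] if e.instance_id in set(chosen)
                ]
                comparison = f"{label} vs {ref_label}"
                profile = consistency_profile(
                    ref_expl, tst_expl, k=config.k, comparison=comparison
                )
                results[(model_name, method, label, "all")] = profile
                for fr, coll in (
                    (profile.to_frame(), cons_frames),
                    (profile.summary_frame(), cons_summary_frames),
                ):
                    fr.insert(0, "method", method)
                    fr.insert(0, "model", model_name)
                    coll.append(fr)
                for metric in ("jaccard", "rank_agreement"):
                    values = profile.jaccard if metric == "jaccard" else profile.rank_agreement
                    res = wilcoxon_signed_rank(values, np.ones_like(values))
                    cons_test_rows.append(
                        {
                            "model": model_name,
                            "method": method,
                            "condition": label,
                            "class": "all",
                            "metric": metric,
                            "test": res.test,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "n": res.n,
                            "degenerate": res.degenerate,
                        }
                    )
                if config.n_per_class > 0:
                    cw_pool = set(np.concatenate(list(classwise_ids.values())))
                    minority, majority = classwise_consistency(
                        [e for e in explanations[ref_label][method] if e.instance_id in cw_pool],
                        [e for e in explanations[label][method] if e.instance_id in cw_pool],
                        labels=labels,
                        k=config.k,
                        n_per_class=config.n_per_class,
                        seed=derive_seed(config.seed, f"classwise:{model_name}:{label}:{method}"),
                        comparison=comparison,
                    )
                    for prof in (minority, majority):
                        results[(model_name, method, label, prof.class_label)] = prof
                        fr = prof.summary_frame()
                        fr.insert(0, "method", method)
                        fr.insert(0, "model", model_name)
                        cons_summary_frames.append(fr)

        # PDPs under the balanced and most-imbalanced conditions
        for label in {ref_label, most_imbalanced}:
            subset = next(s for l, _, s in conditions if l == label)
            stage = f"model:{model_name}:{label}"
            adapter = build_model(model_name, seed=derive_seed(config.seed, stage))
            adapter.fit(subset)
            for feat_name in config.pdp_features:
                spec = cohort.feature(feat_name)
                if spec.kind == "continuous":
                    grid = quantile_grid(subset, feat_name, config.pdp_grid_points)
                    curve = pdp_continuous(adapter, subset, feat_name, grid)
                else:
                    curve = pdp_categorical(adapter, subset, feat_name)
                fr = curve.to_frame()
                fr.insert(0, "condition", label)
                fr.insert(0, "model", model_name)
                pdp_frames.append(fr)
        tick(f"analysis:{model_name}")

    manifest = {
        "config": config.to_jsonable(),
        "master_seed": config.seed,
        "cohort": {
            "n": cohort.n,
            "n_cases": int(cohort.outcome.sum()),
            "prevalence": float(cohort.outcome.mean()),
            "seed": cohort.seed,
        },
        "split": {
            "train_minority": int(train.outcome.sum()),
            "train_majority": int((train.outcome == 0).sum()),
            "test_minority": n_test_minority,
            "test_majority": int((test.outcome == 0).sum()),
        },
        "eval_set": {"n": eval_set.n, "n_per_class": n_eval},
        "subset_total": subset_total,
        "conditions": manifest_conditions,
        "explained_instances": [int(i) for i in chosen],
        "explained_instances_identical_across_conditions": True,
        "classwise_instances": {
            str(cls): [int(i) for i in arr] for cls, arr in classwise_ids.items()
        },
        "stage_seconds": stage_times,
        "versions": _versions(),
    }

    result = SweepResult(
        performance=pd.DataFrame(perf_rows),
        performance_tests=pd.DataFrame(perf_test_rows),
        consistency=(
            pd.concat(cons_frames, ignore_index=True) if cons_frames else pd.DataFrame()
        ),
        consistency_summary=(
            pd.concat(cons_summary_frames, ignore_index=True)
            if cons_summary_frames
            else pd.DataFrame()
        ),
        consistency_tests=pd.DataFrame(cons_test_rows),
        pdp=pd.concat(pdp_frames, ignore_index=True) if pdp_frames else pd.DataFrame(),
        manifest=manifest,
        results=results,
    )
    if config.outdir:
        result.write(config.outdir)
    return result


def _versions() -> dict:
    import sklearn
    import xgboost

    from . import __version__

    return {
        "explainstab": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def consistency_trend(
    seeds=(0, 1, 2),
    **config_overrides,
) -> dict:
    """Does explanation consistency fall as training imbalance grows?

    Runs one sweep per seed, averages each condition's mean Jaccard / Rank
    Agreement across seeds (excluding the balanced reference's trivial
    self-comparison), and reports the Spearman correlation between minority
    proportion and mean consistency for each explainer and metric.  A
    positive correlation says consistency with the balanced reference decays
    as the minority share of the training subset shrinks.
    """
    from scipy.stats import spearmanr

    frames = []
    for seed in seeds:
        cfg = ExperimentConfig(seed=seed, **config_overrides)
        res = run_sweep(cfg)
        summ = res.consistency_summary
        summ = summ[(summ["class"] == "all")].copy()
        prop_by_cond = {
            condition_label(p): p for p in cfg.proportions
        }
        summ["minority_proportion"] = summ["comparison"].str.split(" vs ").str[0].map(
            prop_by_cond
        )
        summ = summ[summ["minority_proportion"] < REFERENCE_PROPORTION]
        summ["seed"] = seed
        frames.append(summ)
    all_summ = pd.concat(frames, ignore_index=True)

    out: dict = {"seeds": list(seeds), "per_seed": all_summ}
    trend = {}
    pooled = (
        all_summ.groupby(["method", "metric", "minority_proportion"])["mean"]
        .mean()
        .reset_index()
    )
    for (method, metric), grp in pooled.groupby(["method", "metric"]):
        rho = spearmanr(grp["minority_proportion"], grp["mean"]).statistic
        trend[(method, metric)] = float(rho)
    out["spearman"] = trend
    return out


def shrinkage_study(
    cohort_n: int = 100_000,
    n_instances: int = 100,
    model: str = "logistic",
    shap_n_permutations: int = 16,
    lime_n_perturbations: int = 400,
    background_cap: int = 100,
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
) -> dict:
    """Attribution shrinkage for minority-class instances under imbalance.

    Trains one model on the original (rare-outcome) training distribution
    and one on its undersampled balanced counterpart, explains the same
    minority-class test instances with both, and compares per-instance mean
    absolute attribution magnitudes.  A model trained under severe imbalance
    predicts low probabilities for cases; since Shapley values decompose
    f(x) − E[f(X)], compressed predictions compress the attributions, so the
    imbalanced model's |attributions| are expected to be systematically
    smaller (one-sided paired Wilcoxon test).
    """
    from scipy import stats as sps

    spec = (cohort_spec or default_lung_cancer_spec()).with_n(cohort_n)
    cohort = generate_cohort(spec, seed=derive_seed(seed, "shrinkage:cohort"))
    train, test = stratified_split(cohort, 0.2, seed=derive_seed(seed, "shrinkage:split"))
    balanced = undersample_balanced(train, seed=derive_seed(seed, "shrinkage:undersample"))

    adapters = {}
    for cond, subset in (("original", train), ("balanced", balanced)):
        a = build_model(model, seed=derive_seed(seed, f"shrinkage:{cond}"))
        a.fit(subset)
        adapters[cond] = a

    minority_pos = np.flatnonzero(test.outcome == 1)
    rng = np.random.default_rng(derive_seed(seed, "shrinkage:instances"))
    if len(minority_pos) < n_instances:
        raise ValueError(
            f"only {len(minority_pos)} minority test instances (need {n_instances})"
        )
    take = np.sort(rng.choice(minority_pos, size=n_instances, replace=False))
    instances = test.frame.iloc[take]

    out: dict = {"n_instances": n_instances, "model": model, "seed": seed}
    for method in ("shapley", "lime"):
        mags = {}
        for cond, subset in (("original", train), ("balanced", balanced)):
            bg_rng = np.random.default_rng(derive_seed(seed, f"shrinkage:bg:{cond}"))
            bg = subset.subset(
                np.sort(bg_rng.choice(subset.n, size=min(background_cap, subset.n), replace=False))
            )
            vals = []
            for iid, row in instances.iterrows():
                if method == "shapley":
                    e = shapley_sampled(
                        adapters[cond],
                        row,
                        bg,
                        n_permutations=shap_n_permutations,
                        seed=derive_seed(seed, f"shrinkage:shap:{cond}"),
                        instance_id=iid,
                    )
                else:
                    e = lime_explain(
                        adapters[cond],
                        row,
                        bg,
                        LimeConfig(
                            n_perturbations=lime_n_perturbations,
                            seed=derive_seed(seed, f"shrinkage:lime:{cond}"),
                        ),
                        instance_id=iid,
                    )
                vals.append(float(e.attribution.abs().mean()))
            mags[cond] = np.array(vals)
        res = sps.wilcoxon(
            mags["original"], mags["balanced"], alternative="less", zero_method="pratt"
        )
        out[method] = {
            "mean_abs_attr_original": float(mags["original"].mean()),
            "mean_abs_attr_balanced": float(mags["balanced"].mean()),
            "shrinkage_ratio": float(mags["original"].mean() / mags["balanced"].mean()),
            "wilcoxon_one_sided_p": float(res.pvalue),
        }
    return out
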
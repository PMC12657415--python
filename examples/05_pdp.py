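"""Partial dependence of predicted risk on age and smoking, balanced vs imbalanced.

Trains the same model family on a balanced and on a severely imbalanced
subset and prints partial dependence side by side.  The imbalanced model's
profile is flattened and shifted down: it has learned mostly that the
outcome is rare.
"""

from dataclasses import replace

from explainstab import (
    build_model,
    default_lung_cancer_spec,
    generate_cohort,
    make_imbalance_subsets,
    pdp_categorical,
    pdp_continuous,
    stratified_split,
)
from explainstab.explainers import quantile_grid

spec = replace(default_lung_cancer_spec(n=40_000), target_prevalence=0.04)
cohort = generate_cohort(spec, seed=1)
train, _ = stratified_split(cohort, 0.2, seed=2)
balanced, one_pct = make_imbalance_subsets(train, (0.5, 0.01), 2000, seed=3)

curves = {}
for label, subset in (("balanced", balanced), ("1% cases", one_pct)):
    model = build_model("random_forest", seed=0).fit(subset)
    curves[label] = {
        "age": pdp_continuous(model, subset, "age", quantile_grid(subset, "age", 5)),
        "smoking": pdp_categorical(model, subset, "smoking_status"),
    }

print("age grid (years) -> mean predicted risk")
for label, c in curves.items():
    pairs = ", ".join(f"{g:.0f}y: {p:.3f}" for g, p in zip(c["age"].grid, c["age"].mean_prediction))
    print(f"  {label:>9}: {pairs}")

print("\nsmoking level -> mean predicted risk")
for level in curves["balanced"]["smoking"].grid:
    row = [
        dict(zip(c["smoking"].grid, c["smoking"].mean_prediction))[level]
        for c in curves.values()
    ]
    print(f"  {level:>16}: balanced {row[0]:.3f}   1% cases {row[1]:.3f}")
# The balanced model's risk rises with age and smoking intensity; the
# imbalanced model's profile is compressed toward its low base rate.
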
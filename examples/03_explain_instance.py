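"""Explain one prediction with LIME and Shapley values and compare rankings.

Trains a logistic model on a balanced subset, explains a single test case
with both methods, and shows the top-5 features of each ranking plus the
Shapley efficiency identity (attributions sum to prediction minus the
background-mean prediction).
"""

from dataclasses import replace

import numpy as np

from explainstab import (
    LimeConfig,
    build_model,
    default_lung_cancer_spec,
    generate_cohort,
    jaccard_top_k,
    lime_explain,
    rank_agreement,
    shapley_sampled,
    stratified_split,
    top_k,
    undersample_balanced,
)

spec = replace(default_lung_cancer_spec(n=30_000), target_prevalence=0.05)
cohort = generate_cohort(spec, seed=1)
train, test = stratified_split(cohort, 0.2, seed=2)
balanced = undersample_balanced(train, seed=3)
model = build_model("logistic", seed=0).fit(balanced)

background = balanced.subset(np.random.default_rng(4).choice(balanced.n, 100, replace=False))
case_row = test.frame[test.outcome == 1].iloc[0]

shap = shapley_sampled(model, case_row, background, n_permutations=50, seed=5, instance_id="case0")
lime = lime_explain(model, case_row, background, LimeConfig(n_perturbations=1000, seed=6),
                    instance_id="case0")

print(f"prediction f(x) = {shap.prediction:.3f}, background mean E[f(X)] = {shap.base:.3f}")
print(f"sum of Shapley values = {shap.attribution.sum():.3f} "
      f"(efficiency gap {shap.efficiency_gap():.2e})")
print("top-5 by |Shapley|:", list(top_k(shap, 5).features))
print("top-5 by |LIME|:   ", list(top_k(lime, 5).features))
r_s, r_l = top_k(shap, 10), top_k(lime, 10)
print(f"LIME-vs-SHAP top-10 agreement: jaccard {jaccard_top_k(r_s, r_l):.2f}, "
      f"rank agreement {rank_agreement(r_s, r_l):.2f}")
# The two methods need not agree perfectly even for one model: they answer
# subtly different questions (local linear slope vs average marginal payout).
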
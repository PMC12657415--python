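"""Stratified split and fixed-size training subsets at controlled imbalance.

Reproduces the subset-construction protocol: an 80/20 stratified split,
then training subsets of identical total size whose minority (case) share
ranges from balanced (50%) down to 1%, plus a random-undersampled balanced
reference.  Minority counts follow round-half-up arithmetic.
"""

from explainstab import (
    default_lung_cancer_spec,
    generate_cohort,
    make_imbalance_subsets,
    stratified_split,
    undersample_balanced,
)
from dataclasses import replace

# a mid-size pool with enough cases for a balanced 2,000-row subset
spec = replace(default_lung_cancer_spec(n=40_000), target_prevalence=0.04)
cohort = generate_cohort(spec, seed=1)
train, test = stratified_split(cohort, test_fraction=0.2, seed=2)
print(f"train: {train.class_counts()[1]} cases / {train.class_counts()[0]} controls")
print(f"test:  {test.class_counts()[1]} cases / {test.class_counts()[0]} controls")

proportions = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01)
for prop, subset in zip(proportions, make_imbalance_subsets(train, proportions, 2000, seed=3)):
    controls, cases = subset.class_counts()
    print(f"  {100 * prop:>4g}% subset: {cases:>5d} cases / {controls:>5d} controls")

balanced = undersample_balanced(train, seed=4)
print(f"undersampled balanced reference: {balanced.class_counts()[1]} per class")
# Each subset has the same total size, so any change in model behaviour is
# attributable to the class mix, not to the amount of training data.
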
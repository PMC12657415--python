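# Methods

This note records the statistical machinery implemented in `explainstab`,
the defaults and why they were chosen, and what conclusions the synthetic
experiments do and do not license.

## 1. Synthetic cohort model

Real primary-care cohorts for rare-cancer risk are access-restricted, so the
package ships a generator that reproduces the *statistical shape* of such
data rather than any real patient distribution.

**Features.** One continuous feature (`age`), one nine-level categorical
(`smoking_status`: Ex Unknown, Ex Light, Ex Moderate, Ex Heavy, Current
Unknown, Current Light, Current Moderate, Current Heavy, Missing — "Missing"
is an ordinary category, not a missing value), and 26 binary
comorbidity/symptom flags (COPD/emphysema, haemoptysis, cough, family
history of lung cancer, …). Age is sampled from a truncated normal on
[30, 90] years (location 62, scale 12) — a screening-age range; no public
reference distribution exists for the real cohorts, so all distribution
parameters and effect sizes are illustrative and should be treated as such.

**Outcome.** Logistic-additive:
`P(Y=1|x) = logistic(c + Σ_j β_j enc_j(x))`, with categorical features
one-hot encoded against their first level. This form was chosen because it
admits closed-form expectations the explainer implementations can be tested
against (e.g. exact Shapley values of a linear model). Effects are largest
for red-flag symptoms (haemoptysis +1.5 log-odds, weight loss +0.9) and
heavy current smoking (+1.2).

**Prevalence calibration.** The intercept `c` is not user-set by default; it
is chosen so the Monte-Carlo mean risk over a 500,000-row feature sample
matches the target prevalence (default 0.6%). The mean risk is strictly
increasing in `c`, so a bracketing root search (`scipy.optimize.brentq` on
[−40, 40]) converges; the residual is checked against a tolerance of 1e-4 on
the prevalence scale. Realized cohort prevalence then deviates from target
only by binomial sampling error plus a small calibration Monte-Carlo error
(~1e-4 absolute).

**Encoding contract.** The one-hot design matrix is part of the cohort
contract: models and all three explainers consume exactly the same encoding,
so attributions are comparable across methods. Explainers attribute at the
*original-feature* level — a categorical feature's one-hot block always
moves as a unit.

## 2. Subset protocol

- **Stratified split**: per class, the test set takes
  `floor(test_fraction × class_count)` rows; this floor convention is what
  makes an 80/20 split of 8,412 cases yield exactly 6,730/1,682.
- **Fixed-size subsets**: the minority count of a proportion-`q` subset of
  total `m` is round-half-up(`q·m`) — the only convention that makes 1% of
  13,460 equal 135. Sampling is without replacement within class.
- **Balanced reference**: random undersampling — all minority rows plus an
  equal-count majority sample. Compositions that do not follow proportion
  arithmetic (e.g. mirroring a source cohort's original counts such as
  82/13,378) are specified through the explicit per-class-count constructor
  rather than guessed from prevalence arithmetic.
- Row identity is the positional index in the source cohort and survives
  every operation, enabling exact partition checks.

## 3. Explainers

**Shapley values.** The value function is the *marginal* (interventional)
estimator: `v(S)` substitutes the instance's values for coalition `S` into
every background row and averages the model output. A conditional-density
formulation is sometimes preferred in theory, but estimating conditional
distributions of mixed clinical features is itself a modelling problem; the
marginal estimator is the deliberate, documented choice here. Exact mode
enumerates all `2^p` coalitions (memoized, batched model calls) and is
capped at p = 12 — beyond that, `2^p` coalition evaluations stop being
desk-scale — above which the permutation-sampling estimator applies
(default 200 permutations standalone; the pipeline uses a smaller
per-config value). Each sampled permutation's marginal contributions
telescope, so efficiency `Σφ = f(x) − E[f(X)]` holds exactly for any number
of permutations; Monte-Carlo error affects only the split across features
(standard error ∝ 1/√n_permutations).

**LIME.** Perturbations: continuous features are standardized against the
background and jittered with unit-variance Gaussian noise around the
instance; categorical/binary features are resampled from the background's
empirical marginals. The surrogate sees the standardized value
(continuous) or a "matches the instance" indicator (categorical/binary), so
a coefficient reads as "effect of being like this patient on this feature".
Proximity is `exp(−D²/w²)` on Euclidean distance in that representation with
the conventional default width `0.75·√d`. The weighted ridge problem is
solved in closed form with the penalty (default 1e-6, a numerical
stabilizer) applied to non-intercept terms only; a rank-deficient design
with zero penalty is reported as an error naming the remedy rather than
silently regularized. The instance itself is always the first perturbation.

**PDP.** Continuous profiles evaluate an explicit grid (the pipeline uses
background quantiles); categorical profiles force every background row to
each declared level in declared order, the reference level being the
all-zero encoding.

**Background samples.** Shapley and PDP backgrounds default to the
explained model's own training subset, subsampled with a seed to a cap
(200 rows standalone, 100 in the pipeline) — explanations thereby inherit
the training distribution, which is precisely the mechanism by which class
rebalancing changes attributions.

## 4. Consistency metrics

Rankings order features by descending |attribution| (mean-|SHAP| is the
standard global criterion, and magnitudes are what clinicians are shown);
`signed=True` switches to raw-value ordering. Ties break by ascending
feature name, making rankings deterministic; when fewer than k attributions
are nonzero, zero-attribution features still fill the ranking and the
explanation is flagged degenerate. "Same relative order" is implemented as
*same rank position* — the reading under which the worked example evaluates
to 3/7 — not as an order-isomorphic subsequence. Union normalization makes
Rank Agreement ≤ Jaccard an algebraic identity (the numerator counts a
subset of the intersection over the same denominator).

Aggregation reports the mean and the standard error (sample SD/√n) over
instances; the class-wise variant selects a seeded fixed-size instance
sample per outcome class.

## 5. Evaluation statistics

- **Youden threshold**: candidates are the distinct observed scores, rule
  `score ≥ t ⇒ positive`; J-ties resolve to the lowest threshold (favoring
  sensitivity — conservative for rare disease). Sensitivity/specificity are
  computed as exact integer ratios so the scan is bit-identical to a
  brute-force count-based oracle.
- **Bootstrap**: resampling is stratified within class so every replicate
  retains both classes; sensitivity/specificity are recomputed at each
  replicate's own Youden threshold.
- **Mann-Whitney U**: exact enumeration when `n_a·n_b ≤ 400` with no ties,
  else normal approximation with midranks, tie-corrected variance and
  continuity correction. Note the protocol applies this test to bootstrap
  replicate distributions, which are not independent samples; the pipeline
  reproduces the protocol as specified and annotates the caveat in its
  output rather than silently "fixing" it.
- **Wilcoxon signed-rank**: zero differences handled by the Pratt method
  (consistency values are bounded, so zero ties are common); exact
  enumeration for n ≤ 12 with no zeros/ties; all-zero differences return a
  flagged degenerate p = 1. No multiple-testing correction is applied — the
  protocol reports raw per-comparison p-values; outputs carry the number of
  comparisons so readers can adjust.

## 6. Pipeline scale and seeding

Every stage derives its seed as `sha256(master_seed || stage_name) mod 2³¹`,
so adding a stage never reshuffles earlier stages' randomness, and a fixed
config yields byte-identical output CSVs.

Default desk scale: cohort n = 40,000, subsets of 2,000 rows, 50 explained
instances, sampled Shapley (16 permutations, 100 background rows), 400 LIME
perturbations, 100 bootstrap replicates. This keeps a full sweep to a few
minutes on one CPU while leaving every stage's logic identical to a
full-scale run. The default *sweep* cohort prevalence is 4%, not 0.6%: a
balanced 2,000-row subset needs 1,000 minority training rows, which a
40,000-row cohort at 0.6% cannot supply (the motivating full-scale cohorts
have ~1.4M rows). The 0.6% prevalence remains the generator default and is
used directly in the attribution-shrinkage study, which trains on the full
imbalanced pool and needs no balanced subset of fixed size.

Model training is the one step delegated to third-party libraries
(scikit-learn, XGBoost): tree ensembles at `max_depth=5`, MLP at library
defaults, plus logistic regression as the analytically tractable workhorse.
Exact constructor arguments are recorded in the run manifest rather than
claiming cross-version equivalence.

## 7. What the synthetic experiments show — and what they don't

The generator produces independently sampled rows from a correctly
specified additive-logistic world with independent features. Passing the
directional tests (consistency decays with imbalance; minority-instance
attribution magnitudes shrink under imbalanced training) demonstrates the
*pipeline measures these phenomena correctly* and that they arise already
from estimation noise and base-rate compression alone — under logistic
regression, undersampling mostly shifts the intercept, so consistency decay
at small minority counts is driven by coefficient estimation variance,
while the shrinkage effect follows from compressed predicted probabilities
(attributions decompose `f(x) − E[f(X)]`, so a model that predicts ~0.01
for every case has little to distribute). Real EHR data adds correlated
features, non-additive risk, coding artifacts and informative missingness;
effect *sizes* measured here do not transfer to real cohorts, only the
measurement machinery does.

Known limitations: no SMOTE/oversampling comparators; no conditional-
expectation Shapley variant; no calibration analysis of the models
themselves; LIME's perturbation scheme is one conventional choice among
several and attributions depend on it.
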
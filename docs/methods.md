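# Methods

This note documents the models and procedures implemented in `aacmodel`,
their assumptions, the tunable parameters that matter, the numerical choices,
and the limits of what the synthetic-data tests can show.

## The choice model

Behavior on the nine-position AAC runway is modeled as a one-shot choice
among terminal positions by a POMDP agent with identity observation
mappings.  Because observations map one-to-one onto states, the ambiguity
component of expected free energy is exactly zero and the valuation reduces
to the risk term:

    V(k) = −KL[ p(o|k) ‖ p(o|C) ]
         = Σ_o p(o|k) ln p(o|C) + H[p(o|k)]

where p(o|k) places probability k/10 on the high-end outcome and 1 − k/10 on
the low-end outcome, and p(o|C) = softmax(u) over the seven observations with
utilities u = points − EC·[aversive], anchored at 0 for the safe positive
outcome and the pre-outcome "starting" observation.  An alternative
valuation that drops the lottery-entropy term (`form="expected_log_preference"`)
is provided behind a switch; every property the test suite relies on
(normalization, shift invariance, EC/DU monotonicity, the CONF4 symmetry at
EC = 4) holds under both forms.  The softmax normalizer of C cancels in
action selection, so the choice of softmaxing over all seven outcomes is
observationally neutral (asserted by a test).

The policy is a Boltzmann distribution,

    p(π = k) ∝ exp( λ · V(k) / DU ),

with DU > 0 the decision-uncertainty temperature and λ a fixed
preference-scale constant (`aacmodel.agent.PREFERENCE_SCALE = 100`).

**Why λ exists and how it was set.**  Raw DU values for this task are
reported with group means near 4–5 alongside strongly position-consistent
behavior: model accuracy near 0.72–0.83 and average action probability near
0.56–0.70.  With V in bare nats (range of a few units across the runway),
temperatures of that magnitude would produce near-uniform policies — model
accuracy ~0.16 in simulation — contradicting those validity figures.  The
two published quantities jointly pin the ratio of valuation range to
temperature, i.e. the unit in which DU is expressed.  λ was therefore
calibrated on a coarse sweep so that cohorts drawn at the published group
parameter moments reproduce the published validity metrics (λ = 16 → accuracy
0.46; λ = 48 → 0.63; λ = 96 → 0.74, action probability 0.67), and fixed at
λ = 100.  Equivalently, one DU unit corresponds to λ temperature units of
the bare-nat valuation.  λ is a model constant, not a free parameter; it is
never fitted.

Excluded by design: multi-step planning, belief updating across trials,
habit terms, and policy-depth features — the task is a single-shot choice
and the model specifies no learning.

## Parameter estimation

(DU, EC) are estimated per subject-visit by MAP in log space,
x = (ln DU, ln EC), which enforces positivity, under an independent Gaussian
prior.  The default prior is weakly informative — mean (0, 0), variance
(4, 4) on the log scale — and fully configurable; study-specific priors were
not available, so the default is declared, not inferred.  The log-joint is
maximized by BFGS with central-difference gradients (step 1e-5) from five
deterministic restarts (prior mean and the four ±1 SD corners), iteration
cap 64 per restart.  The posterior covariance is the inverse negative
Hessian at the optimum (central differences, step 1e-4; Laplace
approximation); a non-positive-definite Hessian falls back to a
pseudo-inverse and clears the `converged` flag.  Policy probabilities are
floored at 1e-12 before logs so the likelihood stays finite for extreme
parameters, and log-parameters are clipped at ±12 inside the objective
(beyond which the policy is numerically at its limit).  A lattice search
over the same log-joint (`fit_grid`) provides an independent oracle; the
test suite asserts the optimizer is never beaten by a 50×50 lattice spanning
the prior's ±3 SD box.

Fit metrics: average action probability (mean model probability of the
chosen position) and accuracy (fraction of trials whose chosen position is a
policy argmax).  Argmax ties credit the subject — any member of the argmax
set counts as correct (tie tolerance 1e-12).  Chance accuracy on nine
positions is 1/9 ≈ 11%.

`optlog_transform` reproduces the skew-minimizing shifted log transform:
ln(x + c) with c selected from {0} ∪ 24 log-spaced points in [1e-3, 1e2] to
minimize |adjusted Fisher–Pearson sample skewness|; a zero-variance input is
assigned skewness 0.

## Behavioral measures and reliability

Model-free summaries per subject-visit, overall and within trial type:
mean chosen position (canonical frame, 9 = cue-adjacent high end, so larger
means more approach), choice variability (SD, n−1 denominator), mean RT.
Choice uncertainty is the policy entropy −Σ p ln p (nats, max ln 9), and its
per-subject Pearson correlation with trial-by-trial RT is the `entropy_rt_r`
feature.  Correlations are undefined (returned as missing with a reason
code) when fewer than 3 usable trials remain or either variable has zero
variance; non-positive RTs are dropped with a warning.  No RT outlier
trimming is applied by default.

Test-retest reliability uses ICC(3,1) — two-way mixed, consistency, single
measures — computed directly from the ANOVA decomposition
(MS_subjects − MS_error) / (MS_subjects + MS_error) with k = 2 visits,
listwise deletion, and at least 3 complete pairs.  Labels: poor < 0.4,
fair 0.4–0.6, good > 0.6.  The implementation is cross-checked against an
independent library computation (pingouin ICC(C,1)) to 1e-10 in the tests.

## Synthetic cohort generator

The generator emulates the study's structure: groups HC / DEP_ANX / SUD,
two visits one year apart, 60-trial design per visit.  Per-group raw-scale
parameter moments are the published group summaries (EC mean±SD 3.53±3.57,
2.97±3.06, 1.69±1.94; DU 3.96±4.65, 4.14±4.57, 5.26±5.72) converted to
log-normal (μ, σ) by moment matching.  Latent log-parameters correlate
across visits at `visit_param_correlation` (default 0.8) with fixed
marginals — a stability knob calibrated for realistic test-retest behavior,
not an estimated quantity.  Attrition removes follow-up datasets with
group-specific probability: HC 0.25, DEP_ANX 0.35, SUD 0.53 (the observed
follow-up return rates), MCAR by default with an optional MNAR tilt on DU.

RTs follow rt = intercept + slope·entropy + N(0, σ), truncated at 0.1 s,
with intercept 1.5 s and noise SD 0.5 s.  Group slopes (HC 0.14, DEP_ANX
0.12, SUD 0.18 s/nat) are calibration presets chosen so the per-group mean
entropy-RT r at n = 300 lands near the published group-level estimates
(≈0.11 for HC and DEP_ANX, ≈0.16 for SUD).

What the generator does **not** emulate: real demographic joint
distributions, symptom scales, comorbidity structure beyond binary labels,
RT dynamics beyond the linear entropy model (no drift, fatigue, or
condition-specific intercepts), and any within-subject learning.  Passing
tests therefore demonstrate internal consistency of the pipeline under the
assumed generative structure — parameter recoverability, calibration of the
classifiers and simulations — not claims about real clinical data.

## Stacked ensemble classifier

Binary diagnostic classification within the clinical sample uses three base
learners — elastic-net logistic regression (standardized inputs; tuned
l1-ratio α ∈ [0,1] and penalty λ with log10 λ ∈ [−4, 1]), k-nearest
neighbors (k ∈ 1..25), and bagged AdaBoost over depth-limited trees
(mfinal ∈ 10..150 boosting rounds, maxdepth ∈ 1..5, 5 bagging rounds by
default).  Hyperparameter candidates are 7 seeded uniform draws per
hyperparameter, crossed into a per-learner grid; the ranges are package
choices.  Evaluation is outer stratified 5-fold CV repeated 5 times.
Within each outer training fold: an inner stratified 80/20 train/validation
split; minority-class up-sampling with replacement applied to training
portions only (never validation or test — audited by a leakage test);
validation AUC selects hyperparameters and sets stacking weights
w ∝ max(AUC − 0.5, 1e-6), normalized, so below-chance learners get ~zero
weight.  The stacked probability is the weighted linear combination of base
probabilities; classification threshold 0.5 with ties toward the positive
class.  Metrics (rank AUC, sensitivity, specificity, balanced accuracy =
their mean) are averaged over folds and repeats.  Variable importance
combines |standardized elastic-net coefficients| with validation-set
permutation importances (5 shuffles) for k-NN and AdaBoost, weighted by the
stack weights and min-max scaled to 0–100.

Five nested predictor sets are supported: (1) age+sex; (2) log-scale EC/DU
at both visits; (3) = 2 + demographics; (4) = 2 + entropy-RT r;
(5) all seven.  Sex is sum-coded (female = −1, male = +1), age centered;
subjects missing any required column are excluded with a count.

## LME power simulation

Outcomes follow y = β₀ + β_g·g + β_t·t + β_gt·g·t + u_subj + ε with sum-coded
group and visit (±1), u ~ N(0, 0.1), ε ~ N(0, 0.9) by default (total
variance 1, so β_g is a quarter of the between-group mean difference
averaged over visits).  Follow-up rows are deleted with probability 0.25
(reference group) and a clinical-group probability defaulting to 0.48
(midpoint of the realistic 0.32–0.64 range).  Each replicate is fitted by
REML (random intercept) and the group term's Wald p-value recorded; power is
the proportion below α = 0.05 with a binomial 95% CI.  Failed fits are
skipped and counted (warning above 5%).  The Wald z test mildly inflates the
null rejection rate relative to a degrees-of-freedom-corrected test
(measured ≈0.059 at 100+100 subjects), which the calibration test's band
accommodates; no small-sample df correction is applied.

## Problem sizes and numerical choices in the test suite

The acceptance-style tests run at sizes chosen for a single CPU: oracle
dominance on 20 subjects with a 50×50 lattice; parameter recovery on a
200-subject cohort (both visits under default attrition, ~330 fits);
classifier null calibration over 20 seeds at n = 400 with a minimal
hyperparameter search (the chance-level property does not depend on search
breadth) and separability/leakage at n = 120; power type-I calibration at
2000 replicates.  Determinism: a single integer seed drives every stochastic
component via `numpy.random.default_rng` / `SeedSequence`; repeated runs are
bit-identical (asserted for the pipeline manifest).

## Known limitations

* The valuation-scale constant λ resolves a unit ambiguity from two
  published summaries; other (scale, temperature-distribution) pairs are
  observationally equivalent, so fitted DU values are only comparable across
  studies up to that unit choice.
* Laplace covariances understate uncertainty when the log-joint is flat
  (very high DU), and the MAP point estimate shrinks toward the prior mean
  there; the recovery report quantifies the net effect.
* ICC(3,1) assumes no subject×visit interaction beyond error; with k = 2
  visits this is not checkable.
* The power simulation treats missingness as MCAR within group, as in the
  simulated design it mirrors; it does not model MNAR drop-out.
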
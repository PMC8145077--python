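# Methods

## The classification procedure

The package implements a two-step classifier for dementia status defined
as global Clinical Dementia Rating (CDR) ≥ 1, learned from a
consensus-diagnosed subsample and applied to undiagnosed participants.

**Step 1.** Candidate probabilistic learners are tuned by repeated
stratified k-fold cross-validation. For each meta-parameter grid point,
out-of-fold predicted probabilities are pooled within each repeat, scored
by AUROC, and the scores averaged over repeats; the winning point is
refitted on the whole training set. Stratification by label is used
because at ~7.6% prevalence unstratified 10-fold splits can produce
single-class validation folds. Observation weights are
`n/(2·n_class)` — equal total mass on each class — wherever the learner
accepts sample weights (the multilayer perceptron does not and trains
unweighted). The risk score is 100 × the predicted probability, clipped to
[0, 100].

**Step 2.** Four clinically motivated strata are attached per person:
depression score strictly above the training 75th percentile, anxiety
score strictly above the training 75th percentile, self-reported vision
impairment, self-reported hearing impairment. For each of the eight
(dimension, membership) cells an F1-maximizing risk-score cutoff is fitted
on the training rows of that cell. The individual receives one weak vote
per dimension (score ≥ the cutoff of their own cell) and is called
positive when ≥ 3 of 4 votes are positive.

Cutoffs are fitted on the **cross-validated training scores** (mean
out-of-fold probability over repeats) rather than in-sample predictions.
This matters: learners such as random forests produce near-0/1 in-sample
probabilities, which would push every fitted cutoff toward 100 and
collapse test-set sensitivity to zero. Out-of-fold scores put the cutoff
search on the same footing as deployment.

Model selection across learners maximizes test-set Cohen's kappa, with
ties broken by F1, then sensitivity, then learner name (full determinism).

## Cutoff-search conventions

* Candidate set: the unique observed scores (the F1 optimum over all real
  thresholds is always attained at an observed score for the ≥ rule).
* Prediction rule: positive iff score ≥ cutoff; a tie at the cutoff votes
  positive, which favours sensitivity.
* F1 with zero true positives is defined as 0 so the argmax is total.
* Equal-F1 ties take the smallest cutoff (maximizes sensitivity at no F1
  cost).
* A cell whose training subset is empty or has no positive cases falls
  back to the full-training-set cutoff; the fallback event is recorded in
  the cutoff table's provenance. A +inf cutoff (no positives anywhere)
  yields an always-negative vote.
* The alternative reading of "group-specific cutoffs" — per-cell cutoffs
  for members only, one shared cutoff for all non-members — is available
  as `mode="member_only"`.

## Evaluation metrics

All metrics are computed from first principles: accuracy, sensitivity,
specificity, precision, F1, Cohen's kappa ((p_o − p_e)/(1 − p_e), marginal
expected agreement), and AUROC as the Mann-Whitney rank statistic with
ties counted ½ (equal to the trapezoidal area under the empirical ROC).
Ratios with empty denominators are reported as NaN and flagged, never
silently zeroed; the F1 := 0 convention lives only inside the cutoff
search. Report tables round half-up to 2 decimals. The clinician
comparison computes per-rater accuracy and kappa against the final
consensus and summarizes them with a t-based 95% CI and a two-sided
one-sample t-test against the model's value; the test behind the
comparison is an interpretive choice (the procedure it mirrors names no
test), and zero cross-rater variance is flagged as degenerate rather than
given a p-value.

## The synthetic cohort

The real survey data are access-restricted, so a generator provides
cohorts with the statistical skeleton the analysis assumes.

* **Latent severity.** One standard-normal factor `z` per participant.
  Global CDR is obtained by cutting `z` at the standard-normal quantiles
  of the cumulative target class probabilities; the default distribution
  is the published class counts (768, 1568, 162, 25, 5)/2528, giving
  P(CDR ≥ 1) = 192/2528 ≈ 7.59%.
* **Scores.** Each continuous score is normal with the published mean/SD,
  shifted by `loading × z`, clipped to its admissible range and rounded to
  instrument granularity (integers; 0.5 steps for the Blessed performance
  scale; the IQCODE and Blessed habits means stay continuous). Because
  clipping at a floor/ceiling biases the mean toward the interior (a
  symptom scale floored at 0 would drift ~+0.3), the pre-clip location is
  solved from the closed-form clipped-normal mean so the generated
  marginal means land on their published values; generated SDs run
  slightly below the published SDs as a consequence of clipping. Binary
  flags are Bernoulli with the published prevalence, shifted on the logit
  scale by `loading × z`.
* **Default loadings** put deficit scores up and ability scores down with
  severity at roughly 0.2–0.6 of each instrument's SD per SD of severity —
  strong enough that a tuned learner discriminates outstandingly
  (AUROC > 0.9) at the study scale, matching the regime the procedure was
  designed for, without being separable.
* **Condition noise.** Independent depression and anxiety symptom factors
  drive the CES-D and anxiety scores and add label-independent deficit
  noise to the cognitive/informant scores; vision and hearing impairment
  flags add mean-centered deficit shifts. This is the confound structure
  that motivates the group-conditional vote step. Centering preserves the
  marginal means.
* **Weights.** Lognormal with log-scale SD `weight_dispersion` (default
  0.5), normalized to mean 1 per cohort; positive and right-skewed with a
  single spread knob.
* **Rater panel.** Each of ≥ 3 raters thresholds `z` plus personal
  N(0, noise_sd) error (round 1). If not unanimous, each dissenting rater
  moves `round2_shrinkage` of the way toward the midpoint of the round-1
  modal class's severity interval and re-rates (round 2); unbounded
  extreme intervals use their finite bound ∓ 0.5 as the representative
  point, and modal ties break toward the lower rating. Cases still
  unresolved go to a consensus meeting, modelled as returning the true
  CDR — the simplest choice that makes consensus labels a clean ground
  truth for agreement studies. Rater defaults (3 raters, noise 0.3,
  shrinkage 0.8) are illustrative; no quantitative description of the real
  panel's error process exists to calibrate against.

**What the generator does not emulate:** the multivariate correlation
structure beyond the single severity factor plus the four condition
confounds; the household/state sampling design behind the real weights;
item-level response processes (instrument scores are drawn directly on the
summary scale); the six-domain CDR algorithm (consensus is simulated on
the global scale, treating the domain-to-global mapping as a black box).
Passing tests therefore demonstrate that the pipeline's operations are
correct and that the two-step procedure behaves as designed under the
assumed signal structure — not that the real survey's performance figures
transfer.

## Instrument scoring

Count-correct instruments (HMSE 30 items, TICS 3, CSID 4, judgment 5,
numeracy, ADL 6, IADL 7, mobility 9) sum binary item indicators; symptom
scales sum item codes (CES-D 10 × 0–3, anxiety 5 × 0–3); informant scales
average item codes (IQCODE 16 × 1–5, Blessed habits 3 × 1–4). The Blessed
performance scale scores each of 8 items 0 / 0.5 / 1: no loss or purely
physical loss scores 0, some loss attributed to mental causes or both
scores 0.5, severe loss attributed to mental causes or both scores 1.
Two documented ambiguities are resolved as follows: the numeracy module is
scored over 9 items to honour its printed 0–9 range (the item count is
configurable for short-form administrations), and severe loss attributed
only to physical causes scores 0, extending the physical-exemption
principle to the severe level. A summary is missing whenever any item is
missing; nothing is prorated, since missing responses are exactly why part
of the real cohort lacks diagnoses.

## Tunable parameters

| parameter | default | notes |
| --- | --- | --- |
| `CVSpec.folds` / `repeats` | 10 / 10 | the study's cross-validation protocol; tests and the acceptance run use 5 × 1 to stay fast — the contract (stratification, out-of-fold scoring) is identical |
| `train_frac` | 0.70 | split size is round-half-up(0.7 n): 2528 → 1770/1770+758 |
| `min_votes` | 3 (of 4) | the majority rule; configurable 1–4 |
| `mode` | `per_cell` | one cutoff per (dimension, membership) cell; `member_only` shares the global cutoff across non-members |
| `class_weighting` | on | equal class mass, sum n |
| learner grids | registry defaults | small (1–2 points per axis); the MLP grid is seeded around one hidden layer of 5 neurons |
| `CohortSpec.n_total` | 2528 | the diagnosed-subsample size |
| `weight_dispersion` | 0.5 | log-SD of sampling weights |
| `condition_strength` | 1.0 | scales all condition-noise effects; 0 removes the confound |
| `RaterSpec` | 3 raters, noise 0.3, shrinkage 0.8 | illustrative |

## Problem sizes in the test and acceptance runs

The suite exercises the generator at n = 50,000 for distributional checks
(chi-square goodness of fit on the CDR classes, severity monotonicity),
weighted-prevalence recovery over 200 cohorts of n = 1,000 (trimmed to the
variables that matter), the full six-learner sweep at n = 2528 with 5-fold
single-repeat tuning, and the vote-step ablation over 20 seeded replicates
at n = 2528 with the gradient-boosting learner. The boosted learner is the
appropriate probe for the ablation because the vote step's benefit is an
overfitting-reduction effect: near-linear learners can absorb the four
condition confounds directly as features, and for them the ablation is a
wash in this synthetic world — a limitation of the single-factor generator
rather than of the procedure.

## Known limitations

* The synthetic two-step gain is small (the win rate hovers modestly above
  one half); the generator's confounds are fully observed by the learners,
  which is kinder than reality.
* No design-based variance estimation for prevalence (the synthetic world
  has no strata/PSU structure).
* The consensus-meeting model (return the true CDR) makes meeting-resolved
  labels error-free by construction.
* The spline-basis logistic learner is a regression-splines-family
  candidate, not the forward/backward adaptive-splines algorithm.
* Learner internals come from scikit-learn; this package owns the
  protocol — weighting, cross-validation, score scaling, cutoff search,
  voting, selection — not the optimizers.
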
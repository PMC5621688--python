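# Methods

## The task and its probability model

The Category Chain is a 4-item simultaneous-chaining task in which each list
position is a *category*: four images (one per category) appear at random
screen positions, the subject must touch them in a prescribed categorical
order, and the first incorrect touch ends the trial. Because the displayed
exemplars are drawn fresh from large image banks, the stimuli are
trial-unique and must be classified before they can be ordered.

Behavior on one trial is summarized by its **progress** k ∈ {0,…,4}, the
number of correct touches before the trial ended (progress 4 = reward). With
conditional accuracies p₁…p₄ (pᵢ = probability the i-th touch is correct
given all earlier touches were), the trial likelihood is the chained product
cut off at the first error:

    P(progress = k) = p₁ ⋯ p_k · (1 − p_{k+1})   for k < 4
    P(reward) = P(progress = 4) = p₁ p₂ p₃ p₄

Expected progress is Σᵢ Πⱼ≤ᵢ pⱼ, identically the mean of the progress
distribution. Under process-of-elimination search (already-chosen items are
not re-chosen), chance accuracy at position i is 1/(4 − i + 1): 1/4, 1/3,
1/2, 1 — giving a chance reward rate of 1/24 (< 5%) and chance expected
progress 5/12 ≈ 0.4167.

Two observation models supply the pᵢ:

* **Stationary** (extensively trained subjects at plateau): pᵢ = logistic(mᵢ)
  with a free logit intercept per position.
* **Learning** (naïve subjects acquiring the task within a session): the
  *asymmetric bounded logistic* (ABL)

      pᵢ(t) = fᵢ + (1 − fᵢ) / (1 + exp(−[sᵢ t + mᵢ]))^{vᵢ}

  with slope s (learning speed), onset m (when performance departs from
  chance), floor f (chance level, fixed at the analytic
  process-of-elimination value by default), and twist v > 0 (asymmetry:
  long floor, sharp acceleration, slow final approach; canonically of order
  e⁶). p₄ is treated as a constant near 1 (default 0.99, configurable),
  since process-of-elimination makes fourth-position errors rare. The twist
  is stored and optimized on the log scale; the power is evaluated as
  exp(v·log σ(x)) with log1p, so v up to e²⁰ stays finite.

t = 0 denotes the first trial of a phase.

## Synthetic data generator

The generator is first-class, tested code; its defaults encode the task
protocol:

* **Sessions** of 40 trials. **Monkey curriculum**: 15 stages that
  progressively un-fix categories (codes `1F-2F-3F-4V` … `1V-2V-3V-4V`, in
  the canonical printed order: four one-varying, six two-varying, four
  three-varying, one all-varying), advancement when the proportion of
  *rewarded* trials in a session meets the criterion (0.80 photographic,
  0.70 painting), then 25 plateau sessions of the full task. The criterion
  statistic is a declared convention: reward is the only scalar per-trial
  success signal, and it is evaluated per single session, advancing on the
  first session that meets it.
* **Painting substages**: the four one-varying stages are each subdivided
  into substages whose varying-category bank holds 2, 5, 10, 25, 50 and
  then 100 exemplars before the unrestricted bank. Banks smaller than a
  40-trial session necessarily reuse exemplars and are sampled with
  replacement; full banks (defaults: 1,000 photographic / 500 painting
  exemplars per category) are sampled trial-unique within a session, and
  exhausting one raises an error unless replacement is explicitly allowed.
* **Human protocol**: one uninterrupted phase of 120 (photographic) or 200
  (painting) trials, no pretraining, all categories varying.
* **Agents** draw each touch independently with probability pᵢ from the
  stationary or ABL model. The sequential-discovery coupling (nothing can
  be learned about item 3 before item 1 is reliably found) is produced by
  *staggered onsets* in the generating parameters, not by an explicit
  gating mechanism — the model describes the cascade, it does not
  mechanize it.
* **Reaction times** are log-normal per position with a linear trend in t
  on the log scale. The monkey preset has descending per-position means
  (log-ms 7.3/7.0/6.8/6.6, no trend) — the within-trial acceleration of a
  process-of-elimination searcher. The human photographic preset drifts
  toward plan-then-execute: the first response slows (+0.25 log units over
  the phase) while later responses speed up (−0.45), i.e. slopes of about
  +0.0021 and −0.00375 log-ms/trial over 120 trials.
* **Cohorts**: learner cohorts draw per-subject slopes log-normally around
  s = 0.1 (σ = 0.5 on the log scale — the large individual differences seen
  in single-session acquisition), onsets normally (s.d. 1.0) around
  staggered means m = (4.0, 2.5, 0.5) chosen so positions 1–3 leave their
  floors near trials ~25, ~40 and ~60 with twist e⁶, and an optional
  non-learner fraction whose onset lies far beyond the phase. Stationary
  cohorts draw per-position accuracies uniform on (0.6, 0.95). One root
  seed; per-subject streams are derived by hashing (seed, subject_id), so
  cohorts are reproducible and independent of cohort size or order.

What the generator deliberately does not emulate: image content and
similarity structure (exemplar ids are opaque integers), backward errors or
repeated touches (the task forbids them), session-to-session motivational
drift, within-trial RT dependence on the chosen exemplar, and any coupling
between accuracy and RT. Passing recovery tests therefore show that the
estimators retrieve the model's parameters from data generated *by the
model* at realistic sizes — not that real subjects obey the model.

## Estimation

The chained likelihood factorizes by position: a trial ending at progress k
contributes a Bernoulli success to positions 1..k and a failure to position
k+1. Each position is therefore estimated from the trials that reached it;
no ad-hoc filtering is applied.

* **Stationary, MLE**: 1-D numeric maximization per position on the logit
  scale (the optimum provably equals the conditional frequency
  correct/reached, which the tests assert to 1e-8). Wald intervals on the
  logit scale; positions with 0 or 100% success are flagged `boundary`
  (interval falls back to full support), positions never reached
  `unidentifiable`.
* **Learning, MLE**: per position 1–3, L-BFGS-B over (s, m, log v) with the
  floor fixed (or a free logit-floor when requested), multi-started from a
  13-point grid over learning speed and onset because the (m, v) profile is
  ridged (for large v the curve approaches a Gompertz in which only
  m − log v is identified). Position 4 is a conditional frequency.
  Intervals come from the finite-difference observed information; a
  singular information matrix is flagged `nonconverged` and estimates are
  still returned.
* **Bayes mode**: the affine-invariant ensemble sampler (emcee) over the
  same likelihoods with weakly-informative priors — logit intercepts
  Normal(0, 2.5); s half-Normal(0.25), m Normal(−5, 5), log v Normal(0, 3),
  all configurable. Draws are seed-reproducible; acceptance fractions are
  reported as diagnostics. The MLE mode exists so the full test suite runs
  without any sampler.
* **Hierarchical fits** are two-stage: independent per-subject fits, then a
  normal-normal random-effects step per (position, parameter) — group mean
  and between-subject variance τ² by Paule–Mandel iteration, subject
  estimates replaced by precision-weighted shrinkage toward the group mean.
  This realizes partial pooling without requiring a joint sampler; a
  statsmodels mixed model serves as an independent cross-check in the test
  suite. A single-subject log falls back to the unpooled fit with a
  warning.
* **Derived summaries**: expected-progress curves propagate posterior draws
  (bayes) or draws from the asymptotic normal of the estimates (MLE — a
  simulation form of the delta method).

## Reaction-time analysis

All RT work is on natural-log milliseconds. Summaries report the mean log
RT with t-based 95% intervals and quantiles per position; RTs below 1 ms or
above 60 s are excluded as apparatus artifacts with a logged count (the
protocol states no exclusion rule; this is the package's convention).
The trend analysis fits log RT = a_pos + b_pos·t per position with
subject-level lines pooled by the same random-effects step as above, and
evaluates the fitted lines at phase start and end, where the
plan-then-execute signature (long first response, fast later responses)
appears. An optional burn-in drops early trials if the early-phase
nonlinearity matters; the default fits all trials. A position-4 RT exists
only on trials with progress ≥ 3; the analysis inherits this missingness
and never imputes.

## Numerical conventions

Probabilities are clipped to [1e-12, 1 − 1e-12] inside likelihood
evaluation only — never in simulation; a structurally impossible outcome
(exact zero probability) yields −∞ with a warning. Exact-1 probabilities
contribute log 1 = 0 unclipped, so a perfect trial has log-likelihood
exactly 0. The chance chain is validated in rational arithmetic
(5/12 exactly). Optimizer bounds: s ∈ [1e-4, 2] per-trial log-odds, m ∈
[−40, 25], log v ∈ [−3, 8].

## Problem sizes used in the test and recovery harnesses

Stationary recovery uses 20 subjects × 1,000 plateau trials; learning
recovery 41 subjects × 120 trials (the photographic human protocol);
RT-regression calibration 50 replicate cohorts of 41 × 120. These sizes
mirror the protocols the generator encodes and give Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* With 120 trials per subject, the ABL slope s is only weakly identified at
  the individual level: its median absolute error (~0.06, and ~0.034 even
  with the twist fixed at truth) is of the same order as realistic
  between-subject spread, so subject-level slopes should be read through
  their intervals or the hierarchical posterior, not as point values. The
  fitted *curves* are nonetheless accurate (pointwise MAE in pᵢ(t) ≈ 0.03).
* m and v are jointly ridged at large v; only their Gompertz combination
  m − log v is sharply determined, which is why both are reported with wide
  intervals on short phases.
* The two-stage hierarchical estimator treats per-subject standard errors
  as known; with very few trials per subject a full joint model would pool
  more efficiently.
* The free-floors option can trade off against the onset m early in a
  phase; it is intended for long phases or pooled fits.
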
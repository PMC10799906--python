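# Methods

## The task and its generative model

The student–teacher task is a restless two-armed choice over a deck of four
cards. Per trial, two distinct cards are offered (uniform over the six
unordered pairs, i.i.d.), the learner picks one, and a reward of 0 or 1 is
drawn from the chosen card's current reward probability. A virtual teacher
privately picks one offered card on *every* trial; the pick is displayed as
advice on a random 60% of trials (i.i.d. Bernoulli — the two presentation
conditions alternate randomly rather than by quota) and hidden otherwise.
The default block structure is 2 sessions × 3 blocks × 130 trials; cards
and teacher are replaced at every block boundary, so every latent
trajectory and every learner state restarts fresh each block.

Latent dynamics are reflecting Gaussian random walks, restarted from a
uniform draw inside their bounds at each block start:

| quantity | bounds | step sd | rationale |
|---|---|---|---|
| card reward probability | [0.25, 0.75] | 0.03 | slow drift; cards never become deterministic |
| teacher inverse temperature β(t) | [1.25, 5.75] | 0.10 | calibrated, see below |

The teacher picks card *i* of the offered pair with probability
`exp(β(t)·p_i) / Σ_j exp(β(t)·p_j)` where `p_i` is the card's *true*
current reward probability. The β-walk runs on β itself (not log β) —
the simplest process consistent with a slowly drifting decision noise.

**Calibration.** The teacher β bounds were chosen by simulating block-level
teacher accuracy (fraction of trials the teacher's draw is the offered card
with the higher true reward probability) across candidate bounds and
selecting the setting whose mean accuracy is ≈63% with block-level
accuracies ranging over roughly 53–77%. With the defaults above, 10,000
simulated blocks give mean accuracy ≈63.3% with a central 95% block band of
≈[51%, 76%] and extremes beyond [53%, 77%]. All walk parameters are plain
`TaskConfig` fields and can be overridden.

**What the simulator does not emulate.** No reaction times are generated
(the `rt` column is empty; RT-based preprocessing applies only to imported
empirical data). Offers are exchangeable across trials (no sequential
structure in which pairs appear), reveal flags carry no autocorrelation,
and the teacher has no trial-order biases. Passing tests on synthetic data
therefore validate the estimation and analysis machinery under the model's
own assumptions; they cannot detect misfit mechanisms absent from the
generator (e.g., choice perseveration or attention lapses in real data).

## The five models

All models share the delta-rule card update and softmax choice; see the
README table for the net-value rules. Conventions that matter:

* **Initialization**: all card and advice values start at 0.5, the midpoint
  of the reward support (config-overridable). With values and rewards in
  [0, 1] and α ∈ [0, 1], every value stays in [0, 1].
* **Update order** within a trial: net values and the choice probability
  from pre-update state → card prediction error from the pre-update value →
  advice-value update (models 3–5, revealed trials only, using that
  δ_card) → card update. All prediction errors use pre-update values; model
  4's |δ_card| moderator therefore refers to the error actually experienced.
* **Concealed trials** use the raw card values in every model: an unseen
  advice cannot enter the valuation. A side effect is that the effective
  card-value weight inside the softmax is β·ω on revealed trials versus β
  on concealed trials for models 3–5.
* **Advice values**: two symmetric values (follow, not-follow); each
  revealed trial updates whichever was enacted. The unadvised card blends
  with the not-follow value. Advice values reset per block (new teacher).
  An alternative — leaving the unadvised card unblended — would break the
  symmetry of the two enacted options; the symmetric blend was chosen.
* **Missing choices** (time-outs): the trial contributes no likelihood term
  and no state update, since no enacted outcome is recorded.
* One learning rate α is shared by card and advice updates.
* Model "2b" (a difficulty-moderated bias) is deliberately not implemented;
  the model registry is the extension point for adding variants.

## Estimation

The default estimator is **two-stage**: per-subject maximum likelihood on
transformed scales (logit α, log β, logit ω, identity φ) with multi-start
L-BFGS-B (default 10 starts: one from the weakly-informative center, the
rest drawn around it), then population mean/sd of the transformed estimates
plus the natural-scale mean. Box constraints on the transformed scale
(|logit| ≤ 7, log β ∈ [−4, 4], |φ| ≤ 5) keep the optimizer off flat
plateaus; solutions at a box edge are flagged, as is a collapsed β (< 0.05),
under which the remaining parameters are unidentified. The likelihood
kernel is numba-compiled; a subject fit takes ~0.1 s.

A **hierarchical** MAP-EM estimator is available: Gaussian population
distributions on the transformed parameters, alternating penalized
per-subject fits with population mean/sd updates (sd floored at 0.05 to
keep the penalty proper). It produces the usual partial-pooling shrinkage
and agrees with two-stage means on well-identified data. It is a
deterministic surrogate for full hierarchical Bayesian estimation, not an
MCMC posterior; no sampler is shipped.

**Model comparison** is leave-one-block-out elpd: for each subject × block,
fit on the remaining blocks, evaluate per-trial log predictive densities on
the held-out block (state freshly initialized — consistent with the
per-block reset everywhere), and sum. Differences versus the best model are
computed pointwise with SE = sqrt(N·var(pointwise diffs)); a winner is
declared only if every rival's deficit exceeds max(4, 2·SE). The predictive
density is a plug-in (point estimates), not a full posterior average; this
typically sharpens differences somewhat but preserves ordering, so the
magnitude of elpd differences should be compared across models, not across
studies. Training fits are per-subject by default.

## Signature analyses

*Coherence* = choosing the teacher's (possibly hidden) pick; the *reveal
effect* is the coherence difference revealed − concealed (per-subject
proportion difference, or a population log-odds estimate).

Population-level estimates come from logistic regressions with a random
intercept per subject, fit by variational Bayes (statsmodels
`BinomialBayesMixedGLM`); reported are the posterior mean, a Gaussian
approximate interval (89% by default — configurable; 89% is merely a
convention for posterior summaries), and the probability of direction (pd),
the approximate posterior mass on the modal sign. The VB optimizer's
internal Monte Carlo draws are pinned to a fixed seed so identical inputs
give identical estimates. Bootstrap-over-subjects intervals are used for
the test–retest correlation (the only non-regression estimate).

* **First-encounter effect**: the reveal-effect regression restricted to
  each block's first concealed and first revealed trial. With a brand-new
  teacher each block, advice-value learning has had no outcomes yet, so
  only the fixed bias φ can produce an effect here.
* **Outcome × presentation interaction**: for consecutive same-block trial
  pairs with the same presentation on both trials, predict whether the
  follow/not-follow behavior repeats from the trial-n outcome, the
  presentation condition, and their interaction, with the teacher's
  trial-n accuracy as a main-effect covariate (controls baseline coherence
  shifts as the teacher drifts). Only outcome-driven advice-value learning
  (ω < 1) predicts a *positive* interaction; in lesioned simulations with
  ω = 1 the estimate is near zero or slightly negative (card-value learning
  interacting with the fixed bias), so the signature is directional:
  positive and decisive (pd ≈ 1) iff the informed channel is active.
* **Teacher-accuracy covariate**: in synthetic data, the indicator that the
  advised card is the offered card with the higher true reward probability
  (a latent column). For imported empirical data without latents, a
  per-block proxy is used: the mean reward obtained on followed revealed
  trials of that block.
* **Lesion simulations**: from fitted (or specified) per-subject
  parameters, simulate under the combined model with φ = 0 (informed
  channel only) or ω = 1 (non-informed only), matched in size to the
  reference dataset, and run both signatures on all three datasets. Pairs
  crossing block or session boundaries are excluded throughout.

## Preprocessing of empirical data

Trials with RT outside [200, 4000] ms are removed; subjects losing more
than 25% of trials this way are excluded; subjects repeating one response
key (or, absent a key column, one screen side) on more than 90% of trials
are flagged but not dropped. Synthetic data without RTs pass through
unchanged. Card indices are 0-based internally; 1-based sources are
remapped on import via an explicit flag, and a thin adapter maps deposited
datasets' column names onto the schema.

## Problem sizes and numerical choices

The shipped experiments use 40 subjects × 4 blocks × 130 trials for
recovery and comparison runs and 60–100 subjects × 6 blocks for the
signature analyses — sizes at which all qualitative results are stable
across seeds while a full pipeline run stays in the minutes range on one
CPU. The default simulation population is α ~ N(0.30, 0.05), β ~ N(6, 1),
ω ~ N(0.70, 0.05), φ ~ N(0.20, 0.05) (clipped to each parameter's support):
ω and φ centered at the winning-model population estimates for this task,
α and β at round mid-range values typical of such fits. Likelihood
equality checks against the brute-force reference implementation hold to
1e−10; softmaxes use max-subtraction and are stable for arbitrarily large β.

## Known limitations

* Point-estimate (plug-in) predictive densities and MAP-EM in place of full
  posterior inference: uncertainty in elpd differences and population
  parameters is understated relative to a fully Bayesian treatment.
* VB posterior approximations for the mixed logistic models can
  underestimate posterior sds, making pd slightly anticonservative; the
  dissociation tests therefore rely on decisive (pd ≈ 1) contrasts, not
  marginal ones.
* The exact latent walk profiles of the original task are not publicly
  specified; only the resulting teacher-accuracy band is matched. Analyses
  that depend on finer properties of the drift (e.g., autocorrelation
  spectra) should re-calibrate `TaskConfig` against their own data.
* Test–retest correlations on simulated stable populations (~0.45 at 60
  subjects) reflect only parameter heterogeneity plus binomial noise;
  empirical test–retest values also contain trait stability not modeled
  here.
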
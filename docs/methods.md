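# Methods

This note documents the generative models, statistical procedures and
numerical choices implemented in `somacross`, and what the synthetic
validation does and does not establish about real data.

## Study design being modelled

A two-intervention (RSS / sham) x two-session (pre / post) crossover
with counterbalanced order. Each participant contributes four cells per
task. Session tables are fixed by the task designs: 64 trials for the
two-point discrimination task (8 probe separations x 8 repetitions,
the single-tip probe encoded as separation 0 mm, which anchors the
lower asymptote of the psychometric curve), 108 for the template
matching task (9 area distortions, 0 and +/-3/6/9/12%, x 12), 40 for
the tactile distance judgement task (2 distances x 2 positions x 10)
and 90 for the tactile localization task (9 locations x 10).

## Stimulation trains

The RSS protocol is a 3 h pulse train whose inter-stimulus intervals
follow a Poisson-process (exponential) law restricted to
[100 ms, 3000 ms]. A plain truncated exponential with rate 1/s has a
truncated mean well below 1 s, so the rate is recalibrated numerically
(Brent root-finding on the closed-form truncated mean, tolerance
1e-12) so that the truncated mean is exactly 1 s; the realized train
rate is then 1 Hz up to renewal-process edge effects (~1e-4 relative).
The sham protocol delivers six 2.5 min blocks (15 min active time)
with the same within-block ISI law. The block placement is not part of
the protocol definition anywhere we could anchor it; blocks are
centred in six equal segments of the 3 h (an even, jitter-free
layout), which fixes total active time exactly and keeps the schedule
deterministic given the seed.

## Synthetic observers

Each simulated participant holds generative parameters for all four
tasks (`ObserverParams`):

* **Binary tasks** respond "two"/"larger" with probability
  `lapse/2 + (1-lapse) * logistic(slope * (x - PSE))`. Note the
  generator lapses but the analysis model does not — the fitting
  layer's robustness to this asymmetry is part of what the recovery
  tests check.
* **Distance judge**: `judged = gain * true + bias (+ tip effect) +
  N(0, sd)`, in mm. Defaults (gain 0.9, sd 4 mm) give the mild
  underestimation typical of tactile distance judgements.
* **Localization observer**: `judged = real + L * (bias_phalanx +
  MVN(0, cov_phalanx))`, with L the finger length. Default biases
  follow the systematic pattern reported for the index finger:
  proximo-ulnar errors on the distal and middle phalanges, radial
  errors on the proximal phalanx; scatter shrinks from base to tip.
* **Intervention effects**: `rss_effects` are additive shifts applied
  in the post-RSS cell only (default: TMT PSE -7.4 area-%, 2PDT
  threshold -0.3 mm); sham shifts nothing.
* **Session fluctuation**: cell-wise zero-mean jitter of the
  thresholds. For the TMT PSE this jitter is a scaled Student-t with
  3 df (scale 5 area-%). The heavy-tailed choice reconciles three
  features that a Gaussian cannot express simultaneously with a
  +/-12% stimulus range: most cells stay well inside the range, the
  residual spread of PSE changes is large (standardized intervention
  effects of ~0.7-1), and the occasional session lands far enough
  outside the range that the cell becomes unfittable — so a small
  number of participants (typically 1-6 of 33) are excluded exactly
  the way real unfittable participants are.

Phalanx lengths default to equal thirds of the finger length and are
configurable per participant. All generators are bitwise-deterministic
given (parameters, seed).

What the generator does **not** emulate: sequential/order effects
within a session, learning or fatigue, response-time structure,
non-stationary lapse rates, finger geometry beyond a single length
scale, and any correlation between tasks within a participant beyond
what the shared design induces. Passing recovery tests therefore show
that the analysis chain is correct and well calibrated for data of
this structure — not that real data satisfy the model.

## Psychometric fitting

Maximum-likelihood logistic regression on per-trial binary outcomes
(statsmodels GLM/binomial; identical optimum to fitting aggregated
percentages, with cleaner convergence diagnostics). PSE = -b0/b1;
the probability slope at the PSE is b1/4. A cell is unfittable when
the optimizer fails, |b1| < 1e-8, the deviance is ~0 (perfect fit of
binary data = complete separation, where the ML slope is unbounded),
or the fitted 50% point lies more than one stimulus-range width
outside the tested range (a near-flat profile whose threshold is not
measurable from the data). Any unfittable cell excludes the
participant from that task entirely, so the crossover models see
complete cases only. The inference layer receives b1 as "the slope";
b1/4 is exported alongside.

## Localization analysis

Both axes are normalized by finger length: a single isotropic scale
preserves angles, which the direction analysis requires. Sign
convention: +x radial (thumb-ward), +y distal; reported tables name
directions (ulnar/radial, proximal/distal) rather than bare signs.

The constant-error direction is the angle of the *mean displacement
vector* (atan2 of mean dy, mean dx), not the circular mean of
per-trial angles: the former is stable when per-trial angles are noisy
at small magnitudes; the per-trial circular mean is available as
`circular_mean_direction`. The confidence ellipse uses the
chi-square(2 df) quantile without a small-sample F correction; with
>= 7 trials per condition the difference is small.

Cleaning rules: missed trials are removed and tallied; per-trial
outliers beyond 3 SD of their own condition on either axis are
screened; every condition must retain at least 7 of its 10 trials
(hard error otherwise, naming the cell). Group-level outliers
(participant mean displacement magnitude beyond 3 SD of the group) are
flagged but retained, so analyses can run both with and without them.
The group screen uses leave-one-out SDs: a single extreme participant
would otherwise inflate the SD it is judged against and mask itself,
which matters at pilot-scale n.

## Crossover inference

* **LMMs** (statsmodels MixedLM, REML). Fixed part: the full factorial
  of session, intervention and the task factors. Random part ladder:
  intercept + session + intervention slopes -> intercept +
  intervention slope -> intercept only; each fallback step is recorded
  in the fit handle. Several optimizers (lbfgs, powell, cg) are tried
  because gradient methods can fail when a variance component sits on
  its boundary.
* **Type-II Wald chi-square**: each term is tested as in the model
  without its higher-order relatives, expressed as a linear hypothesis
  on the full fit (the hypothesis matrix absorbs the relatives'
  columns through the projection that aliases them onto the tested
  term). This matches the R `car::Anova(type=2, test="Chisq")`
  construction and, on balanced data with negligible random effects,
  equals df x F from classical ANOVA.
* **EMM contrasts**: estimated marginal means are balanced-weight cell
  predictions from the fixed effects; contrasts are tested with
  t-statistics on the residual-df approximation
  (df = n_obs - n_fixed_coefficients). A Satterthwaite approximation
  would be preferable in principle; statsmodels exposes no machinery
  for it, and at this design's sizes (>= 120 observations, <= 36
  coefficients) the residual-df t is close to normal, so the
  approximation is inconsequential. alpha_Bonf = 0.05 / family size;
  the standard families are post-pre within intervention (2), phalanx
  pairs (3), locations (9) and ellipse pairs (36), giving the printed
  0.025 / 0.017 / 0.006 / 0.0014.
* **Effect sizes**: Cohen's-d-like, contrast estimate divided by the
  LMM residual SD. For Wald terms an eta-squared analogue is reported
  as chi2/(chi2 + residual df); this is a pragmatic partial
  variance-explained measure, clearly labelled, since no standard
  definition exists for LMM terms.
* **Post-pre slopes**: the same linear combination as the EMM
  contrast, with a Wald (normal-quantile) 95% CI; a CI excluding zero
  flags an intervention effect.
* **JZS Bayes factors**: Cauchy(0, 0.707) prior on the standardized
  effect; BF10 is the prior-weighted noncentral-t density of the
  observed t divided by the central-t density, integrated by adaptive
  quadrature split at the integrand's peak (absolute tolerance 1e-6).
  Cross-checked in tests against pingouin and a Monte-Carlo
  prior-sampling oracle.
* **Harrison-Kanji circular two-way ANOVA**: resultant-length
  decomposition over the 2x2 cells. When the pooled concentration
  estimate kappa > 2 (tight angles), an ANOVA-like F variant with the
  1/(1 - 1/(5k) - 1/(10k^2)) correction is used; otherwise the
  low-concentration chi-square variant with doubled dfs and the
  2/(1 - rbar^2) scaling. Degenerate samples (all angles equal) are
  reported as a flagged no-effect table. Null calibration of both
  t-tests and the circular test is verified by simulation in the test
  suite (type-I error 0.05 +/- 0.02 at 1000 replicates).

## Problem sizes used in validation

Null-calibration simulations use 400 replicates for the mixed-model
interaction test (each replicate a 20-participant study) and 1000 for
the circular ANOVA and one-sample tests; effect recovery uses 300
replicates of a 31-participant measure-level study with an injected
-7.4 interaction and residual SD 10.1 (the spread implied by a
standardized effect of 0.73 for a 7.4-point shift), plus five
full trial-level studies at n=33. Monte-Carlo oracles use 1e5 draws
(ellipse coverage) and 8e6 antithetic prior draws per grid point
(Bayes factors).

## Known limitations

* No Satterthwaite/Kenward-Roger dfs (see above).
* The Harrison-Kanji high-concentration F variant is asymptotic; at
  very small cell sizes its calibration is untested here.
* The pipeline expects complete 2x2 cells per participant; partial
  crossovers are dropped rather than modelled.
* Order (carryover) effects are generated and recorded but only
  testable through the generic paired-test utilities, not modelled in
  the LMMs.
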
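# Methods

This note documents the models, estimation procedures, synthetic-data
generator and numerical choices behind `popigt`, in the order the pipeline
runs them.

## Task environment

The Play-or-Pass IGT presents one deck per trial; a play draws the next
outcome in that deck's fixed sequence, a pass (or a 4-second timeout, coded
as a pass) leaves the $2,000 bank unchanged. The payout magnitudes and trial
count of the published task are not public, so the package defaults to the
classic four-deck block structure: bad decks pay +100 per play (deck A
spreads five losses of −150…−350 over each 10-play block; deck B carries one
−1250), good decks pay +50 (deck C: five −50, i.e. $0 cards; deck D: one
−250), i.e. −250/+250 net per block, over 120 trials with 30 presentations
per deck. Every element is configurable; the shipped presentation order was
drawn once (seeded) with each deck appearing once per 4-trial group and is
frozen in `data/default_task.yaml`. Two task versions permute the mapping of
physical deck positions to payout schedules; all analyses run on canonically
recoded logs (A/B bad, C/D good), and canonical summary statistics are
version-invariant by construction.

A consequence of this payout structure worth noting: win/loss *frequency* is
balanced across the good and bad pairs (B and D are both rare-loss decks, A
and C both frequent-loss), so the frequency-sensitivity parameter has no
structural association with net proportion play in data generated with
independently drawn parameters. Positive β_f–performance correlations in
real cohorts therefore reflect between-person parameter covariation rather
than task structure, and the association tests assert only the robust
punishment-learning effect.

## PoP-ORL model

State: per-deck expected value EV (delta rule on outcome/`outcome_scale`,
default scale 100) and expected frequency EF (delta rule on sign(outcome)).
Value of playing deck j: `V_j = EV_j + EF_j*beta_f + beta_b`; value of
passing 0; choices Bernoulli(logistic(V)). The learning rate is valence
gated: A_rew for outcomes ≥ 0 ($0 cards count as gains, with sign target 0),
A_pun for losses. With `fictive_updating` on (default), the three
non-presented decks receive EF updates toward `−sign(outcome)/3` using the
opposite-valence rate, mirroring the parent outcome-representation model's
frequency mechanism; a flag disables it. The play probability for each trial
is computed from the state *before* that trial's update, and passes produce
no update. Likelihood evaluation uses a numerically stable log-logistic form
in a numba-compiled loop, verified against a literal trial-by-trial
reference implementation to 1e-10; no probability clipping is needed.

Defaults chosen where the published model's update equations are not in the
open literature we reproduce: Rescorla–Wagner deltas, outcome/100 scaling,
fictive updating on with attenuation 3. These are structural defaults, not
fitted values, and the validation suite passes with fictive updating on or
off.

## Hierarchical estimation (`map_eb`)

Each wave is fit separately. Subject parameters live on an unconstrained
scale (probit-linked learning rates, identity-linked betas) with a normal
population prior per coordinate. The default backend proceeds:

1. **Flat pass** — per-subject penalized MLE under an effectively flat prior
   (SD 10), multi-start L-BFGS (3 starts, jitter 0.5·SD keyed to session
   content so identical data get identical estimates), with a fused
   objective/gradient evaluated inside the jit. Per-coordinate sampling
   variances come from likelihood-only curvature (diagonal Laplace; flat
   directions capped at variance 400 so uninformative data are downweighted,
   not discarded).
2. **Group step** — the population mean and SD of each coordinate are first
   estimated by marginal-ML deconvolution of the flat estimates
   (N(θ̂; μ, τ²+se²)), then refined by Monte-Carlo marginal maximum
   likelihood: 256 importance draws per subject from a defensive mixture of
   a local (curvature-scaled) and a population proposal, with the exact
   likelihood evaluated per draw and (μ, τ) maximizing the self-normalized
   marginal-likelihood estimate. This is the same integral a full
   hierarchical sampler targets; naive moment updates of MAP points were
   measured to collapse the group SD for weakly identified coordinates and
   are not used.
3. **Shrinkage pass** — subject MAP estimates under the fitted group prior,
   iterated to stability (tolerance 1e-3 on the estimates).

Rates are clipped to [1e-6, 1−1e-6] before the probit transform. Optimizer
nonconvergence is flagged per estimate, never silent. The optional `mcmc`
backend replaces step 3 with per-subject affine-invariant ensemble sampling
(emcee) under the converged group prior and reports posterior means; it
approximates, but does not replicate, a jointly sampled non-centered
hierarchical model, which would require a probabilistic programming backend.

Measured behaviour at the default design (100 subjects × 120 trials):
true-vs-recovered correlations ≈ 0.5–0.75 for A_rew (median ≈ 0.62 across
seeds), ≈ 0.8–0.9 for A_pun and β_b, ≈ 0.5–0.75 for β_f. The A_rew floor is
intrinsic: population draws below probit −2.2 (A_rew < ~0.01) are
unidentifiable in 120 trials, and oracle-prior and posterior-mean estimators
sit at the same ceiling. Group SDs are recovered well; group means for the
weakly identified coordinates can deviate by a few SE at n=100.

Point estimates (not posteriors) feed the growth stage, as the two-stage
design prescribes; joint trial-level/growth modelling is out of scope. The
price of the two-stage design is shrinkage attenuation: within-wave
contrasts of fitted estimates are compressed by a reliability factor λ
relative to the truth (measured λ ≈ 0.50/0.45/0.65/0.75 for
A_rew_z/A_pun_z/β_f/β_b at the full design).

## Growth models

For each metric, a ladder of ML-fitted (never REML, so nested LRTs are
valid) linear mixed models with subject random intercepts and age slopes:
unconditional linear (1), unconditional quadratic (2), the LRT winner plus
maternal-history main effect and age interaction(s) (3), plus IQ, sex and
administration-modality covariates (4). Age is centred at the constant
10.98 years — the design's average baseline age — so group effects are
"baseline effects" at that age; the centre is deliberately not recomputed
from input data. Model 1 selects the random-effect structure through a
singularity cascade (full covariance → uncorrelated → intercept-only,
recorded on the fit); models 2–4 share that structure with warm-started
covariance parameters, so LRT df equal the fixed-effect difference and
log-likelihood chains stay monotone. Constant covariate columns are dropped
as inestimable. Fixed-effect t tests and CIs use residual df
(n_obs − n_fixed); ICC is τ00/(τ00+σ²) from the unconditional means model;
pseudo-R² (total) is the squared correlation between observations and
conditional predictions including random effects — a common definition,
documented here because none is canonical. Age-effect p-values for the four
computational parameters are BH-adjusted as one family; the model-4-vs-
unconditional LRT is emitted against both model 1 and model 2 (the winner's
comparison is the headline one).

The engine is a profiled-ML fitter specialized to the (1, age) random
structure (`_lmm.py`): the relative random-effect covariance is
Cholesky-parameterized, β and σ² are profiled out per evaluation via the
Woodbury identity in a numba loop, leaving a ≤3-parameter search. It agrees
with statsmodels MixedLM to ~1e-5 in log-likelihood and coefficients (the
test suite enforces this) and is ~10× faster, which is what makes the
replication studies below affordable.

## Synthetic cohort generator

The generator emulates the study design: 208 baseline participants split
between 9–10 and 12–13-year recruitment cohorts, five waves 0.75 years
apart, monotone missing-at-random attrition to (208, 157, 135, 98, 73)
(rescaled proportionally for other sample sizes), maternal-depression-
history prevalence 0.36, IQ ~ N(101.8, 15), 59% female, fully on-site
administration at waves 1–3 and 89%/41% on-site at waves 4–5. True
parameters per subject-wave follow linear effect maps on the generating
scales (intercept + age and quadratic terms + risk offset + covariate
effects + subject random intercept + wave-level noise), with learning rates
mapped through the standard-normal CDF; sessions are then simulated from
those parameters on the fixed schedule.

Two calibrations fix the free constants of the effect maps, both performed
once and frozen:

* **Effect sizes.** Intercepts are the published-scale typical-condition
  values; contrast coefficients (age slopes, risk offsets, covariate
  effects) are the target *fitted* effects divided by the measured
  attenuation λ above, because the two-stage pipeline shrinks within-wave
  contrasts — generating with the fitted-scale values directly would yield a
  synthetic study with roughly half the intended effect sizes. With the
  disattenuated maps, the default full-scale study estimates age(A_rew_z)
  ≈ −0.04, age(β_f) ≈ +0.3 and hx(A_rew_z) ≈ −0.06, as intended.
* **Stability.** Subject-level and wave-level SDs were set so that fitted
  test–retest reliability of the computational parameters lands in the
  poor-to-fair band (measured r ≈ 0.2–0.5 across adjacent wave pairs at the
  default design), matching the repeatability this class of task shows over
  nine-month gaps.

What the generator does *not* emulate: practice effects across repeated
administrations, pubertal or medication covariates, non-monotone missingness
or covariate-dependent dropout (an optional mode exists for the latter), and
real-data correlations *between* parameters beyond those induced by shared
age/risk/covariate structure. Passing recovery tests on this cohort
therefore demonstrates that the pipeline estimates what the generative model
encodes — not that the published participant-level coefficients are
reproduced, which no synthetic study can show.

## Validation studies and their measured behaviour

* Likelihood oracle: jit core ≡ reference loop to 1e-10 (100 random
  sessions).
* BH-FDR: matches the brute-force step-up definition on 1000 random vectors.
  (BH adjustment is not idempotent — [1.0, 0.25] adjusts to [1.0, 0.5],
  which re-adjusts to [1.0, 1.0] — so the property tests assert
  monotonicity, dominance and determinism instead.)
* Growth-model CI coverage: 95% intervals on a known age slope cover truth
  at nominal rate over 200 simulated panels.
* Parameter recovery: median over three seeds at 100 subjects × 120 trials,
  thresholds 0.59 (A_rew) / 0.6 (others).
* Full-pipeline sign recovery: 50 scaled-down replications (120 baseline
  subjects); the three hallmark signs are each recovered with measured
  per-replication probability ≈ 0.90 (A_rew age slope), ≈ 0.96 (β_f age
  slope) and ≈ 0.88 (risk offset on A_rew), jointly ≈ 0.78–0.82. The joint
  ≥ 90% criterion is intrinsically marginal at this scale: the risk offset's
  target fitted magnitude (−0.06) is ~1.2 sampling SEs at n=120 with ~43
  risk-group subjects, so its sign recovery cannot reach ~0.95 per
  replication without changing the study conditions. The test asserts the
  90% threshold as designed and is expected to sit near, sometimes below,
  it.

Problem sizes throughout (100-subject recovery waves, 120-subject
replication studies, 200-panel coverage runs) are the package's validation
defaults, chosen to make the full suite a coffee-break run on one core.

## Known limitations

* Empirical-Bayes MAP is not full MCMC: posterior uncertainty is not
  propagated downstream (by design, matching the two-stage analysis), and
  group means of weakly identified coordinates carry finite-sample bias.
* The update equations and payout schedule are reconstructions of a task
  lineage, not a byte-level replication of the unpublished originals;
  exact numerical agreement with the published cohort is out of reach and
  out of scope.
* Residual-df t tests are an approximation (no Satterthwaite correction);
  with ~650 observations the difference is negligible.
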
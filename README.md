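# popigt

Reinforcement-learning analysis of the **Play-or-Pass Iowa Gambling Task**
(PoP-IGT) for developmental studies: task simulation, hierarchical fitting of
the four-parameter **PoP-ORL** model, traditional summary scoring, and
multilevel growth modelling of performance trajectories across adolescence,
including a maternal-depression-history risk moderator. A synthetic
accelerated-longitudinal cohort generator stands in for participant data, so
every stage of the pipeline can be validated end to end against known ground
truth.

## The task and the model

On each trial one of four card decks is offered and the participant *plays*
(drawing a net monetary outcome) or *passes* (bank unchanged). Two decks lose
money on net (canonical labels A, B), two gain (C, D); deck order and outcome
sequences are fixed, so all behaviour is in the play/pass choices. Traditional
scoring summarizes a session as the proportion of plays on good decks, on bad
decks, and their difference (*net proportion play*).

The PoP-ORL model decomposes those choices. Each deck *j* carries an expected
value *EV* (magnitude-sensitive) and an expected win/loss frequency *EF*
(sign-sensitive), combined into the value of playing

&nbsp;&nbsp;&nbsp;&nbsp;V<sub>jt</sub> = EV<sub>jt</sub> + EF<sub>jt</sub>·β<sub>f</sub> + β<sub>b</sub>,

with the value of passing fixed at 0 and choices Bernoulli on the logistic of
V. Delta-rule updates use the reward learning rate A<sub>rew</sub> after
gains and the punishment learning rate A<sub>pun</sub> after losses;
β<sub>f</sub> weighs outcome *frequency* ignoring magnitude and
β<sub>b</sub> is a constant go bias. The model is fit hierarchically per
assessment wave (empirical Bayes with normal population priors on an
unconstrained scale; learning rates probit-linked), and the probit-transformed
learning rates join the betas and the traditional scores as outcomes in
random-intercept-and-slope growth models over age (centred at 10.98 years),
compared by likelihood-ratio tests and FDR-corrected where exploratory.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(`python analysis/01_simulate_cohort.py` through `06_growth_trajectories.py`,
a few minutes altogether, outputs under `results/study/`). The same pipeline
is available as a CLI: `popigt all --seed 11 --outdir results/study`.

Simulation and fitting (steps 01–02):

```
simulated 671 sessions ([208, 157, 135, 98, 73] per wave, seed 11)
baseline: mean age 10.89, 39% maternal depression history, 61% female
...
per-wave mean estimates:
      A_rew  A_pun  beta_f  beta_b
1     0.061  0.071   3.658   1.156
...
5     0.034  0.068   7.666   1.721
```

Reward learning rates are low (~0.05) and drift lower with age while
frequency sensitivity rises — the developmental pattern the generator
encodes. Model validation (step 04) recovers the generating parameters:

```
parameter recovery (true vs recovered, n=100 x 120 trials):
  A_rew   r = 0.70
  A_pun   r = 0.84
  beta_f  r = 0.60
  beta_b  r = 0.78
recovered A_rew vs beta_f correlation: -0.06 (near zero = parameters dissociable)
posterior predictive check: observed play proportion inside the simulated 95% interval in 94% of deck x block cells
```

and the growth ladder (step 06) estimates the trajectories:

```
   metric    winner  age_coef  age_fdr_or_p  hx_coef   hx_p   icc
      net    linear    0.0095        0.0019  -0.0097 0.3542 0.169
  A_rew_z    linear   -0.0375        0.0012  -0.0803 0.0273 0.313
   beta_f quadratic    0.3651        0.0003  -0.5715 0.0141 0.153
  ...
```

Net play improves with age (+0.010/year); the reward learning rate declines
(−0.038/year on the probit scale) and is lower in youths with a maternal
history of depression (−0.080 at the average baseline age, p = .027) — the
three hallmark effects the synthetic cohort is built to carry, recovered here
from raw simulated choices.

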
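# Methods

This note documents the models, the synthetic-data generator, the
estimation machinery and the design decisions in `cogrel`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task models

### Restless four-armed bandit

Each trial the agent picks one of four arms and can receive a reward
(coded 1/0), a punishment (coded −1/0), both, or neither; the two outcomes
are independent Bernoulli draws from the chosen arm's current win and loss
probabilities. The winning model in this family is five-parameter
Q-learning with lapse:

* `a_rew`, `a_pun` ∈ [0,1] — learning rates for reward and punishment
  prediction errors. Only the chosen arm updates:
  `Q_rew[c] += a_rew·(r_sens·reward − Q_rew[c])`, and likewise for
  punishment.
* `r_sens`, `p_sens` ∈ [0,30] — multiplicative outcome sensitivities in
  Q-value units. They double as inverse temperature: the softmax over
  `Q_rew + Q_pun` has its temperature fixed at 1, because a free
  temperature would be redundant with the sensitivities
  (identifiability).
* `xi` ∈ [0,1] — lapse: with probability ξ the choice is uniform, so
  every arm's probability has floor ξ/4.

Q-values reset to zero at the start of each session; sessions are
modelled as independent realisations of the same subject.

Reduced variants (shared learning rate, shared sensitivity, no lapse, and
their combinations) are expressed through `ModelSpec` toggles that expand
a reduced parameter vector to the canonical five-parameter form; they
exist for model comparison, not as claims about any particular published
variant's exact equations.

### Calibrated gambling task

Offers are a 50–50 gamble against a sure amount; mixed trials pit a gain
against a loss (sure option 0), gain-only trials a gain against a sure
positive amount. Prospect-theory utility with risk aversion ρ ∈ (0,2),
loss aversion λ ∈ (0,5) and inverse temperature τ ∈ (0,30):
`u(x) = x^ρ` for gains, `−λ(−x)^ρ` for losses, and
`p(gamble) = logistic(τ·(EU_gamble − u(sure)))`. Only the calibrated
(second-phase) trials enter model fitting; the training phase exists to
locate indifference points. Variants fix ρ or λ at 1.

## Synthetic studies

The generator is the ground-truth side of every test: it draws subject
parameters from known group distributions with known between-session
correlations, simulates both tasks, and emits the same tidy CSV schemas
the fitting code reads.

* **Latent scale.** All parameters live on an unbounded latent scale and
  map to their bounds by `x = lo + (hi−lo)·Φ(z)`. The generator and the
  fitter share one implementation (`transforms`), so generated populations
  are exactly the populations the hierarchical model assumes; a round-trip
  latent → native → latent is identity to numerical precision.
* **Between-session structure.** For each parameter, a subject's
  (session 1, session 2) latents are bivariate normal with the specified
  correlation — the generating value of every reliability estimand
  downstream.
* **Defaults.** Group means on the native scale: learning rates ≈ 0.40 /
  0.30, sensitivities ≈ 6 of the 0–30 range, lapse ≈ 0.05 with a
  deliberately small spread (lapse varies little between healthy
  subjects, which is precisely what makes it poorly recoverable and
  unreliable); ρ ≈ 0.9, λ ≈ 1.5, τ ≈ 0.25 in point-utility units.
  Default between-session correlations sit in the good-to-excellent range
  for learning rates, sensitivities and the prospect-theory parameters,
  and 0 for lapse.
* **Environments.** Win and loss probabilities follow independent
  reflecting Gaussian random walks, default step SD 0.03 within
  [0.2, 0.8] — gradual drifts with lag-1 autocorrelation above 0.9 —
  8 independent trajectories per environment. Each subject-session gets
  its own environment realisation by default (a shared-schedule switch
  exists); independent walks avoid environment-induced between-subject
  correlation.
* **Calibration.** Phase-1 responses (fixed grid: 50 mixed offers spanning
  loss/gain ratios 0.25–4, 40 gain-only offers spanning sure/gain
  fractions 0.1–0.9) are fit by maximum likelihood with the
  prospect-theory rule; the mixed indifference ratio and the gain-trial
  sure/gain fraction (`0.5^(1/ρ̂)`) centre symmetric phase-2 grids of
  64 mixed and 56 gain-only offers. A subject who always gambles or never
  gambles in a trial type is assigned the grid midpoint and flagged. ML
  calibration was chosen over a staircase because it is deterministic and
  directly testable by parameter recovery.

What the generator does **not** emulate: within-session learning of the
task structure, attention drift, motor errors beyond the lapse mixture,
any point-to-money conversion, or the exact offer grids of any particular
experiment. Passing tests therefore demonstrate that the pipeline
recovers what it assumes — the standard validation logic of simulation
studies — not that real data satisfy those assumptions.

## Hierarchical estimation

Per session, subject latents are `z_i = μ + σ·η_i` (non-centred), with
priors `μ_p ~ N(0,1)` and `σ_p ~ half-N(0.2)` on every (bounded)
parameter. A pooled mode fits both sessions' subject-sessions under a
single prior as a sensitivity analysis.

The **joint two-session model** replaces the independent prior by, per
parameter, a bivariate normal over the (s1, s2) latent pair whose 2×2
correlation matrix has a uniform prior on its off-diagonal (LKJ shape 1
restricted to 2×2). Reliability is the posterior of that correlation.
Subject point estimates from the joint model exist but are *not* used for
reliability — correlating them would double-count the shared prior. The
per-parameter 2×2 structure (rather than one full cross-parameter matrix)
keeps the estimand aligned with one correlation per parameter; a full
matrix would add nuisance cross-correlations without changing the
diagonal blocks of interest.

**Sampler.** Posteriors are drawn with a blocked adaptive random-walk
Metropolis-within-Gibbs scheme: all subjects' latent vectors are proposed
at once and accepted subject-wise (valid because subjects are
conditionally independent given group parameters), group-level scalars
update one at a time, and proposal scales adapt only during warmup
(Robbins–Monro toward 25% block / 44% scalar acceptance). The bandit
likelihood is a compiled kernel; the prospect-theory likelihood is
vectorised, so a study-sized fit takes seconds. In the joint model the
subject latents are explicit (centred parameterisation) — the natural
blocking there, since group-level updates then touch only the bivariate
prior, and with 120–200 informative trials per subject-session the
centred geometry mixes well. Chains initialise from ridge-stabilised
per-subject maximum-likelihood estimates with per-chain jitter.

Defaults: 4 chains × (1500 warmup + 1500 kept); the test profile uses
2 × (700 + 700). A random-walk sampler needs more sweeps than a
gradient-based one; these counts give stable group-level estimates at
study sizes (N ≤ 50, 120–200 trials) while keeping the full test suite
in minutes. Both profiles are recorded in run metadata.

**Diagnostics.** Split-R̂ and bulk ESS (arviz) for every group-level
quantity, flagged above R̂ = 1.1; per-subject marginals are scanned for
multimodality by comparing 1- vs 2-component Gaussian mixtures (flag when
the 2-component BIC wins by a margin, default 6) — a reproducible stand-in
for visual inspection of posteriors.

**Recovery.** `parameter_recovery` simulates → fits → correlates truth
with posterior means. With the default population, learning rates and
sensitivities recover well (r ≈ 0.8–0.95 at N = 30 × 200 trials in the
acceptance run) while lapse recovers poorly — expected, since its
generating spread is small.

## Model comparison

Candidates are scored by LOOIC = −2·elpd_loo with Pareto-smoothed
importance sampling over per-draw, per-trial log-likelihoods
(leave-one-trial-out; a config switch to leave-one-subject-out is the
natural alternative and changes only the column grouping). Observations
whose log-likelihood is constant across draws get the exact leave-one-out
value (constant importance ratios), which also covers degenerate
single-draw candidates. The fraction of Pareto k > 0.7 is reported per
candidate.

## Model-agnostic measures and GLMM ICC

Stay probabilities condition trial *t* on the outcome class of trial
*t−1* (win-only, loss-only, neither); trials whose previous outcome was
"both" are excluded from the three classes but kept in model-based
likelihoods (the three-class analysis is standard; the model uses all
trials). Empty classes are missing, never zero. Gamble rates are simple
proportions by trial type on calibrated trials.

The trial-level counterpart is a mixed-effects logistic regression with
random intercepts for subject and subject-within-session fit to both
sessions jointly; `ICC(1) = σ²_subject / (σ²_subject + σ²_subj-within-sess)`.
The default estimator maximises the exact marginal likelihood by adaptive
Gauss–Hermite quadrature (each subject contributes a 2-D integral over
its session-intercept pair, evaluated at mode-centred, curvature-scaled
nodes; 12 nodes per dimension). The quadrature agrees with brute-force
numeric integration to ~1e−9, and the estimator matches lme4's
`glmer` variance components to four decimals on identical data.
statsmodels' variational and Laplace fits remain available behind
`method=`, but the mean-field factorisation collapses the subject
component of nested intercepts and the joint-mode (MAP) variance
estimates are erratic, so neither is the default. Random slopes are
deliberately omitted from the default structure: the measure-specific
ICCs condition on a single trial class, leaving nothing for a slope to
capture; the fixed-effect structure (condition main effects) is
configurable. A per-session mode returns subject random-intercept
estimates for use with the classical paired ICC estimators.

## Classical reliability statistics

ICC(A,1) (two-way, single-measure, absolute agreement) and ICC(1)
(one-way random effects) with F-based 95% CIs follow the standard
mean-squares formulation (computed via pingouin; the test suite checks
them against an independent ANOVA mean-squares oracle to 1e−6). Zero
total variance yields a missing estimate rather than a number. Pearson
correlations carry Fisher-z intervals. Practice effects: paired t,
Cohen's d_z = mean(diff)/sd(diff), and repeated-measures ANOVA with
partial η²; sphericity corrections are not applied (exact for two-level
factors; reported uncorrected for the three-level outcome factor).
Bands: < 0.40 poor, 0.40–0.60 fair, 0.60–0.75 good, > 0.75 excellent.

The power analysis uses the noncentral-t formulation of the one-sample
correlation test (noncentrality `ρ√n/√(1−ρ²)` against the central-t
criterion at df = n−2) and searches for the smallest adequate n; for
ρ = 0.4, one-tailed α = 0.05, power 0.90 it returns 47. The exact-null
t formulation reproduces this classical figure, which is why it was
adopted over simulation-based power.

## Posterior-predictive forecasting

Accuracy is the mean probability the model assigns to the choices a
subject actually made in session 2, with Q-values evolving along the
observed session-2 history. Predictors are posterior-mean point estimates
(a draws-averaged mode exists behind a flag); the "other" baseline
averages probabilities per trial across all other subjects' parameter
sets before averaging over trials, and the "prior" baseline uses the
posterior mean of the native-scale group location parameter. Chance is
0.25 (bandit) and 0.5 (gamble); paired t-tests compare own vs chance,
own vs other, own vs prior.

## Numerical and interface choices

* CSVs: comma-separated, UTF-8, header row, empty cell for missing;
  1-based trial and arm indices. Schema violations raise errors naming
  the offending row and column.
* All randomness flows through seeded NumPy generators; run metadata
  records seed and config, and outputs carry a hash of the scientific
  configuration (the output path is excluded from the hash).
* The latent↔native transform saturates in float64 beyond |z| ≈ 5;
  inverse transforms clip to the open unit interval.
* Degenerate inputs: empty trial sequences, single-subject hierarchies,
  mismatched rosters and invalid outcome codings raise typed errors;
  degenerate calibration responders fall back to grid midpoints with a
  flag; zero-variance reliability inputs report missing.

## Known limitations

* The sampler is random-walk based: posterior *tails* of weakly
  identified quantities (e.g. the lapse group SD) mix more slowly than a
  gradient-based sampler would; group-level locations and the embedded
  correlations — the quantities the pipeline reports — are stable at the
  default sweep counts, and diagnostics surface the rest.
* The inverse-temperature ICC on small synthetic cohorts is noisy: τ is
  the least constrained prospect-theory parameter when offers sit near
  indifference, which is faithful to calibrated designs.
* Joint-model reliability assumes bivariate-normal latents; heavy-tailed
  individual change would be attributed partly to unreliability.
* Model variants are a configurable family (toggles over shared rates,
  sensitivities, lapse, fixed ρ/λ), not equation-level reproductions of
  any specific published variant set.
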
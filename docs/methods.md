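# Methods

This note documents the models, the estimation machinery, the synthetic
cohort generator, and the numerical choices behind `socialrisk`, in enough
detail to audit or extend any stage.

## Task structure

A session crosses four lottery menus (drawn per subject without replacement
from eight), six high-payoff probabilities (0.40–0.90 in steps of 0.10) and
four trial types (solo, info-safe, info-risky, info-mix), giving 96 trials
— 24 per type — in a subject-unique random order. Each menu is a payoff
quadruple (v_high_safe, v_low_safe, v_high_risky, v_low_risky) with
v_high_risky > v_high_safe > v_low_safe > v_low_risky, which guarantees the
riskier lottery has strictly greater payoff variance at every probability
level. The default family scales the classic Holt–Laury pair
(2.00/1.60 vs 3.85/0.10) by eight multipliers (1.00–2.75 in steps of 0.25);
the payoffs are fully overridable via config because no model quantity
depends on the specific values, only on the spread ordering.

Social information is reduced to the unanimity indicator δ (+1 when both
displayed players chose the safer gamble, −1 when both chose the riskier,
0 on solo and mixed trials). The identities of the displayed players are
deliberately not represented: every model consumes only δ.

Choice coding: `choice = 1` is the safer gamble, so every model is written
as P(safe).

## Choice models

All four models share power utility U = p·v_high^α + (1−p)·v_low^α and a
softmax over the safe-minus-risky utility difference with inverse
temperature β. The other-conferred-utility (OCU) model adds δ·OCU inside
the softmax; the value-free heuristic model replaces the choice rule on
unanimous trials with constants ω_follow (info-safe) and ω_oppose = 1 −
ω_follow (info-risky); the hybrid model mixes the two routes through a
simplex (ω_follow, ω_oppose, ω_utility):

* info-safe: P = ω_follow + ω_utility · P_OCU
* info-risky: P = ω_oppose + ω_utility · P_OCU
* solo / info-mix: P = P_OCU

The nesting is exact: hybrid with ω_utility = 1 is the OCU model; OCU with
OCU = 0 is the solo risk-preference model. The test suite asserts these
identities to 1e−12 and the implied probability bounds
(P ∈ [ω_follow, 1 − ω_oppose] on info-safe, mirrored on info-risky) over
random draws.

Group-level free-parameter counts used in model comparison: solo 4, OCU 6,
OCU-free 5, hybrid 8 (two hyperparameters per pooled parameter, plus free
weights, minus the simplex constraint).

**Likelihood clamping.** Safe-choice probabilities are clamped to
[1e−9, 1 − 1e−9] inside every likelihood. Without this, ω_follow = 1 plus a
single discordant choice yields an infinite negative log likelihood; the
clamp bound is configurable (`PriorConfig.clamp`) and its value is far
below any probability resolvable from 96 Bernoulli trials.

**Naming.** The risk-preference exponent is called `alpha` throughout; the
same quantity is often written ρ in reporting contexts.

## Hierarchical estimation

Subject-level parameters are sampled on unconstrained scales: log β, log α
(exponential transform), OCU (identity), and weights through an
additive-log-ratio transform (logit for the single OCU-free weight). Each
of log β, log α, OCU is pooled across all subjects by one group-level
Gaussian with weak hyperpriors μ ~ Normal(0, 10) and σ ~ half-Cauchy(0, 2.5)
(scale parameterization). When group labels are supplied, additive offsets
with Normal(0, 10) priors shift the log β group mean for each non-reference
group; the offset is placed on the log (pre-exponential) scale. Weights are
not pooled: each subject's weights carry an independent uniform prior on
the simplex, implemented in unconstrained coordinates with the exact ALR
Jacobian (log w_f + log w_o + log w_u). Optional hard bounds (e.g.
β ∈ [0, 50], α ∈ [0, 2]) can be imposed via `PriorConfig.bounds` and are
enforced by proposal rejection.

### Sampler

No Hamiltonian backend is required: the posterior is sampled by an adaptive
Metropolis-within-Gibbs scheme, fully vectorized across chains and
subjects, with four ingredients per sweep:

1. **Subject blocks** — joint random-walk Metropolis on each subject's
   unconstrained coordinates (two proposals per sweep). Per-(chain,
   subject) scalar step sizes multiply fixed per-coordinate base scales and
   adapt toward 25 % acceptance during burn-in (Robbins–Monro on the log
   step).
2. **Group means and offsets** — exact conjugate Gibbs draws (Gaussian
   likelihood in the subject-level coordinates, Gaussian priors).
3. **Group SDs** — random-walk Metropolis on log σ with the half-Cauchy
   prior and log-scale Jacobian, adapted per (chain, parameter).
4. **Interweaving** — a second (μ_h, σ_h) update in the non-centered frame:
   holding z = (θ − μ − offset)/σ fixed, a joint proposal moves the
   hyperparameters and the whole subject block together, accepted against
   the full likelihood. Centered and non-centered frames have complementary
   pathologies (the "funnel"); alternating them is the standard
   ancillarity–sufficiency interweaving strategy and empirically collapsed
   the worst split-R-hat on the OCU hierarchy from > 2 to < 1.4 at 1000
   retained draws per chain.

Chains initialize at per-subject penalized maximum-likelihood estimates
(multi-start Nelder–Mead on the unconstrained scale with a weak Gaussian
ridge, SD 2.0, to regularize separable subjects) plus chain-specific
jitter (SD 0.3 on subject coordinates, 0.2 on hypers) so the convergence
diagnostic starts from genuinely dispersed points. The MLE fitter
(`fit_mle`) is also exposed as an independent point-estimate oracle; the
tests cross-check posterior medians against it.

Defaults follow the 4 chains × 5000 draws / 2000 burn-in layout (12,000
retained draws); the recovery protocols and tests run reduced layouts
(4 × 1500/500 or 2 × 1200/400) whose sizes are stated where used.
Convergence is summarized by split R-hat (arviz) over all hyper- and
subject-level quantities; any R-hat ≥ 1.1 marks the summary non-converged —
a visible warning on the object, never a silent pass. Divergent transitions
are a Hamiltonian-specific diagnostic; the summary carries a `divergences`
field (always 0 for this sampler) to keep the reporting interface uniform.

**Point estimates.** Per-subject estimates are elementwise posterior
medians on the natural scale. Componentwise medians of simplex weights do
not sum to one, so they are renormalized; the pre-normalization deficit is
recorded per subject (`weight_median_deficit`) and is typically < 0.05.
The per-subject fit metric is the negative log likelihood at these medians;
the solo-trial version under the solo risk-preference model is the
"disruption" score used in group comparisons and correlations.

## Model comparison (iBIC)

The integrated BIC evaluates each model's *marginal* likelihood under its
fitted group-level distribution rather than at a point estimate. For
subject i, K parameter draws θ_k come from the estimated group Gaussians
(medians of μ, σ, and the subject's group offset), with weights drawn
uniform on the relevant simplex, and

    log m_i = logsumexp_k [ log L_i(θ_k) ] − log K,
    iBIC = −2 Σ_i log m_i + k_group · log(N_choices),

where k_group is the group-level free-parameter count above and N_choices
the total number of choices (subjects × trials). K defaults to 2000
(warning below 100); the Monte-Carlo standard error shrinks as 1/√K, which
the tests verify empirically. The exact iBIC variant (placement of the
hyperparameter count and sample-size term) is a convention; this one is
stated in every report so alternatives can be swapped.

Individual-level model attribution (for confusion/inversion matrices) uses
the per-subject analogue −2·log m_i + k_individual·log(96), with
k_individual = 2/3/3/5 for solo/OCU/OCU-free/hybrid. The confusion matrix
normalizes best-fit counts within each simulated model (rows sum to 1);
the inversion matrix normalizes within each fitting model (columns sum
to 1).

## Synthetic cohorts

The generator emulates a three-group lesion study: non-lesion controls
(n = 28) plus insula-like (n = 10) and dACC-like (n = 6) groups. Per-agent
parameters are drawn from group hyper-distributions — log-normal β and α,
normal OCU, and uniform-simplex weights rejection-sampled into a per-group
range box. Defaults (all config-overridable, and never claims about any
empirical cohort):

| group | log β | weight box (follow, oppose, utility) |
|-------|-------|--------------------------------------|
| NC | N(log 3.0, 0.5) | [0, .4], [0, .35], [.45, 1] |
| INSULA / DACC | N(log 1.2, 0.5) | [.25, .85], [0, .4], [.05, .55] |

Shared defaults: log α ~ N(log 0.85, 0.3), OCU ~ N(0.2, 0.4). The
lesion-like groups are noisier (lower β ⇒ worse solo utility fit) and
follow-shifted — the qualitative direction the cohort is meant to express,
verified by the direction tests (info-safe safe-rate > solo > info-risky;
higher conformity distance for follow-heavy populations).

**Exclusion rules** (a-priori, applied to simulated behavior exactly as to
participants): (i) a subject whose riskier-choice proportion at the 90 %
win level is strictly below that at the 40 % level is excluded (ties keep;
computed over all trials by default, solo-only available as the
sensitivity-analysis variant); (ii) a subject choosing all-safe or
all-risky on the 24 solo trials is excluded (bi-directional social
influence impossible). `simulate_until_valid` redraws an agent's
parameters and re-simulates until the slot passes, recording the resample
count per subject.

**What the generator does not emulate:** response times, demographics
(age, cognitive screens), lesion anatomy, session-level nonstationarity
(fatigue, learning), or any dependence of choices on previous trials.
Passing tests therefore certify the estimation and testing machinery under
the model's own data-generating assumptions, not robustness to the
violations real data would bring.

## Recovery protocols

*Parameter recovery*: 44 agents are drawn from a single recovery population
(defaults: the shared hyper-distributions above with weights uniform on the
full simplex), simulated under the hybrid model over fresh randomized
sessions, passed through the exclusion/resampling loop, and refit
hierarchically (no group offsets, as no labels exist). Six correlations
are reported: truth vs posterior-median log β, α, normalized OCU
(logistic(β·OCU), each side using its own β), and the three renormalized
weights. An option pins per-slot β values, mirroring protocols that reuse
empirical temperatures.

Under these defaults the weight, temperature and risk-preference
correlations are strong (r ≈ 0.7–0.94 across seeds) but **normalized-OCU
recovery is weak (r ≈ 0.0–0.6, typically ~0.4)**. This is a property of the
study conditions, not the estimator: the independent no-pooling MLE oracle
achieves the same correlation, and restricting to agents with
ω_utility > 1/3 roughly doubles it. With weights uniform on the simplex,
the average agent routes only a third of unanimous-trial behavior through
the OCU term, whose effect is then largely absorbed by the follow/oppose
weights; OCU is identified only through the gamble-value dependence of its
influence. Recovery studies seeded from a fitted cohort in which the
utility route dominates would express OCU far more strongly. The package
reports this correlation as computed rather than selecting conditions that
flatter it.

*Model recovery*: cohorts are simulated from each of the four models in
turn and refit by all four; the group-level iBIC table, subject-level
confusion matrix and inversion matrix are reported, with non-converged fits
flagged per cell. At the scales exercised in the tests (two models × 20
subjects; reduced chains) the generating model attains the lowest group
iBIC and the largest row proportion — the nested structure makes stronger
individual-level dissociation unrealistic, and no such claim is asserted.

## Resampling statistics

All tests share one two-tailed convention: p = #{|null| ≥ |observed|} /
n_iter (ties count toward the null; floored at 1/n_iter), with n_iter =
10,000 by default and every routine reproducible from (seed, n_iter).

* **Group tests** (pooled t with pooled-variance statistic; one-way ANOVA F
  for ≥ 3 groups — the specific F variant is our choice): all values pooled,
  resampled with replacement into pseudo-groups of the original sizes.
  Type-I error under exchangeable nulls is verified at 0.05 ± 0.02 over 500
  replicate datasets.
* **Association tests** (Pearson r, OLS slope): the null "unpairs" x and y
  by resampling each independently.
* **Chi-squared**: group labels redrawn from the pooled category
  distribution at fixed group sizes; Pearson X² statistic.
* **Skipped (robust) correlation**: bivariate outliers flagged by
  projecting all points onto the direction of each point from the
  coordinatewise-median center and applying the 1.5·IQR boxplot rule per
  projection (union over directions); Pearson r on the retained points;
  p from the unpaired bootstrap on retained points. The plain Pearson r is
  reported alongside. This flavor was chosen for transparency and
  testability; it agrees with the MCD-based skipped correlation in
  pingouin to ~0.1 on clean data (cross-checked in the tests).
* **Null Bayes factors**: default-prior JZS (Cauchy scale √2/2) via
  pingouin, reported as BF_null = 1/BF10; an independent quadrature oracle
  of the JZS marginal verifies the t-test version in the suite.
* **Residualization**: OLS residuals on intercept + covariates
  (statsmodels), for covariate-controlled reruns of any test.

## Reproducibility and problem sizes

Every stochastic stage derives its generator from a global seed plus a
stage tag (CRC-32 keyed SeedSequence), so pipeline reruns are
bit-reproducible; every output file embeds the config hash and seed. The
test suite and the acceptance script run reduced problem sizes chosen as
the smallest at which each property is stable: recovery at 4 × 1500/500
draws, model recovery at two models × 20 subjects with 2 × 1200/400 draws,
end-to-end direction checks at 14 + 14 subjects, bootstrap calibration at
500 replicates × 2000 iterations. Headline analyses on real-scale data
should use the 4 × 5000/2000 defaults.

## Known limitations

* Random-walk MCMC mixes more slowly than gradient-based samplers; at the
  reduced chain lengths used in tests, split R-hat occasionally exceeds 1.1
  for the weakest-identified quantities (flagged, not hidden). Longer
  chains resolve this.
* Normalized-OCU recovery under the default generator conditions is weak
  (see above).
* The OCU-free and hybrid models are exactly nested and the confusion
  matrices reflect that: individual-level attribution between them is
  unreliable by construction.
* The bootstrap group test assumes exchangeability under the null; it is
  not a permutation test (resampling is with replacement) and its p-values
  inherit Monte-Carlo granularity of 1/n_iter.
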
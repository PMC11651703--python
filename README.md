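# socialrisk

Tools for studying **socially situated decision-making under risk**: how
people choosing between a safer and a riskier gamble combine their own risk
preferences with the observed choices of others — and what happens to that
combination when utility-based risk processing is disrupted (as in
individuals with insular or dorsal anterior cingulate lesions).

The package provides, as a tested, reusable pipeline:

* a **gambling-task generator** (Holt–Laury-style lottery menus × six win
  probabilities × four trial types: solo choices and choices after seeing
  two other players both pick safe, both risky, or split);
* four **nested choice models** for the probability of picking the safer
  gamble;
* **hierarchical Bayesian estimation** of all models by MCMC;
* **integrated-BIC (iBIC)** model comparison plus parameter- and
  model-recovery simulation;
* a **pooled-bootstrap statistics toolbox** (t/F/correlation/regression/
  chi-squared nulls, skipped robust correlation, JZS null Bayes factors,
  covariate residualization);
* a **synthetic-cohort generator** standing in for participant data, with
  the study's a-priori behavioral exclusion rules.

## The models

Each trial presents two lotteries sharing a win probability `p`; the riskier
one has the wider payoff spread. Power utility with risk preference α
(α < 1 averse, 1 neutral, > 1 seeking) values each lottery,

    U = p · v_high^α + (1 − p) · v_low^α,

and a softmax with inverse temperature β turns the utility difference into a
choice probability. The four models, from most restricted to full:

| model     | P(safe) | free parameters (group level) |
|-----------|---------|------------------------------|
| `solo_rp` | σ(β(U_s − U_r)) | 4 (μ, σ for β, α) |
| `ocu`     | σ(β(U_s − U_r + δ·OCU)) | 6 (+ μ, σ for OCU) |
| `ocu_free`| ω_follow / ω_oppose on unanimous trials, solo rule otherwise | 5 |
| `hybrid`  | ω_follow·1 + ω_oppose·0 + ω_utility·P_OCU (info "safe"); mirrored on info "risky"; P_OCU otherwise | 8 |

Here σ is the logistic function, δ ∈ {+1, −1, 0} indicates unanimous
safe/risky information, OCU ("other-conferred utility") is an additive bonus
on the option others chose, and (ω_follow, ω_oppose, ω_utility) is a simplex
of mixture weights separating *value-free* conformity from utility-routed
social influence. On unanimous trials the weights bound the reachable choice
probability: P(safe) ∈ [ω_follow, 1 − ω_oppose] when others chose safe.

Estimation is hierarchical: log β, log α and OCU are pooled through
group-level Gaussians (μ ~ Normal(0, 10), σ ~ half-Cauchy(0, 2.5)), with
additive group-difference offsets on the log-β mean for lesion-like groups;
weights carry an individual-level uniform-simplex prior. Sampling uses an
adaptive Metropolis-within-Gibbs scheme with conjugate hyper updates and an
interweaved non-centered step (see `docs/methods.md`), vectorized across
chains and subjects.

## Worked example

Simulate a two-group cohort (utility-dominant controls versus a noisier,
follow-shifted lesion-like group), refit the hybrid model, and test the
headline contrasts:

```python
import numpy as np
import pandas as pd
import socialrisk as sr
from socialrisk.hierarchical_inference import McmcConfig, median_params, solo_fit_metric

rng = np.random.default_rng(0)
groups = [
    sr.GroupSpec(label="NC", n_subjects=12, mean_log_beta=np.log(3.0), sd_log_beta=0.5,
                 weight_box={"w_follow": (0.0, 0.4), "w_oppose": (0.0, 0.35),
                             "w_utility": (0.45, 1.0)}),
    sr.GroupSpec(label="INSULA", n_subjects=8, mean_log_beta=np.log(1.2), sd_log_beta=0.5,
                 weight_box={"w_follow": (0.25, 0.85), "w_oppose": (0.0, 0.4),
                             "w_utility": (0.05, 0.55)}),
]
cohort = sr.simulate_cohort(groups, model="hybrid", rng=rng)

mcmc = McmcConfig(n_chains=4, n_draws=1500, n_burnin=500, seed=7)
fit = sr.fit_hierarchical("hybrid", cohort, mcmc=mcmc, group_map=cohort.groups)

med = median_params(fit)
wf = pd.Series({s: med[s].w_follow for s in fit.subject_ids})
grp = pd.Series(cohort.groups)
res = sr.bootstrap_group_test([wf[grp == "INSULA"], wf[grp == "NC"]], "t",
                              n_iter=10_000, seed=1)

solo_fit = sr.fit_hierarchical("solo_rp", cohort, mcmc=mcmc, group_map=cohort.groups)
nll = solo_fit_metric(solo_fit, cohort)
rc = sr.robust_correlation(nll[fit.subject_ids].to_numpy(), wf.to_numpy(),
                           n_iter=10_000, seed=2)
```

Output from this exact run:

```
subjects: 20
max R-hat: 1.404
median w_follow  NC: 0.163   INSULA: 0.394
pooled-bootstrap t = 2.63, p = 0.0169
solo -LL vs w_follow: skipped r = 0.34, p = 0.1463 (0 outliers removed)
```

Reading it: the lesion-like group's posterior-median follow weight is more
than double the control group's, and the pooled-bootstrap t-test (null built
by resampling all 20 subjects' weights into pseudo-groups of sizes 8 and 12)
calls that difference significant. The per-subject solo-trial fit of the
pure utility model (−LL at posterior medians; larger = worse utility-based
choice) correlates positively with the follow weight — the direction
expected when conformity substitutes for disrupted utility computation —
though at n = 20 this run's correlation is not individually significant.
The max R-hat of 1.40 flags imperfect mixing at this reduced chain length;
`fit.converged` is False and longer chains (the 4 × 5000/2000 defaults)
should be used for reportable numbers.

The same pipeline is scriptable from the shell:

```bash
socialrisk simulate --config config.yaml --out results/
socialrisk fit --model hybrid --data results/choices.csv --out results/
socialrisk stats --data results/choices.csv \
    --hybrid-medians results/medians_hybrid.csv \
    --solo-medians results/medians_solo_rp.csv --out results/
```

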
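# beliefgrid

Model-based analysis of **belief updating** in a perceptual learning task,
with synthetic single-trial ERP regression.

In the task, a checkerboard's contrast sweeps linearly up and down the
screen and the participant stops it to choose a contrast. A hidden target
contrast pays out according to a symmetric triangular mapping — 25 cents at
the target, falling to 0 beyond a 15% contrast difference:

    R(r_t, x_t) = round(25 − 5|r_t − x_t| / 3)  if |r_t − x_t| < 15, else 0

Because the participant never learns exactly which contrast they chose,
learning is modeled by a **Bayesian grid estimator under response
uncertainty**: beliefs about the target are a PMF θ_t over J = 148 contrast
bins on [10, 100]%, and after feedback f_t the belief is updated by

    θ_{t+1}(j) ∝ θ_t(j) · Σ_{j*} 1[R(c_j, c_{j*}) = f_t] · G_0(x_t, c_{j*}, σ)

where G_0 is a zero-mean Gaussian (SD σ, the response-uncertainty
parameter) weighting every contrast the participant might believe they
chose. Choices follow the belief blurred by the same Gaussian
(Pr(x_t) = (θ_t ∗ G_0)/k). A one-parameter win-stay/lose-shift heuristic is
the comparison model, fitted by maximum likelihood and compared by BIC.

From the fitted belief trajectory the package derives, per trial:

| variable | meaning | definition |
|---|---|---|
| `H`  | belief uncertainty | Shannon entropy of the prior (bits) |
| `I`  | belief update size | H(prior) − H(posterior) (bits) |
| `I_KL` | Bayesian surprise | KL(prior ‖ posterior) (nats) |
| `S`  | feedback surprise | −log2 Pr(f \| x, θ) (bits) |

The ERP side works on synthetic feedback-locked epochs with planted
effects (a P3-like bump tracking `I`, a pre-feedback negativity tracking
`−H`): single-trial amplitudes (P3 = 300–450 ms max; SPN = −500–0 ms mean,
each baseline-corrected) are z-normalized per participant and regressed on
the belief variables with robust bisquare IRLS; participant betas get
Bonferroni-corrected one-sample t tests, plus a 3 (trial stage) × 2
(median-split update size) repeated-measures ANOVA control.

Intended users: computational cognitive neuroscientists who want a tested,
reusable reference implementation of this modeling-plus-single-trial-ERP
pipeline, or a planted-effect sandbox for validating similar analyses.

## Worked example

```python
import pandas as pd
from beliefgrid import (make_grid, init_prior, feedback_likelihood, bayes_update,
                        entropy, update_size_mi, simulate_cohort,
                        fit_sigma, compare_models)

grid = make_grid(10, 100, 0.61)           # 148-bin contrast space
prior = init_prior(grid)                  # uniform belief at block start
post = bayes_update(prior, f=20, x_true=50.0, sigma=15.0)
j = grid.bin_index(60.2)                  # bin centered at ~60.2% contrast
lik = feedback_likelihood(grid, 20, 50.0, 15.0)
print(f"prior mass     theta_1({j+1}) = {prior.pmf[j]:.3f}")
print(f"likelihood     Pr(20c, 50% | r in bin {j+1}) = {lik[j]:.3f}")
print(f"posterior mass theta_2({j+1}) = {post.pmf[j]:.3f}")
print(f"entropy drop   I = {update_size_mi(prior, post):.3f} bits "
      f"(H: {entropy(prior):.3f} -> {entropy(post):.3f})")

trials = simulate_cohort(n_participants=4, agent="bayesian", sigma=13.0,
                         n_blocks=6, seed=0)
fits = [fit_sigma(tab, model, seed=0, participant_id=pid)
        for pid, tab in trials.groupby("participant")
        for model in ("unbiased_updating", "wsls")]
summary = compare_models(fits)
print(f"sigma-hat: {[round(f.sigma_hat, 2) for f in fits if f.model_name == 'unbiased_updating']}")
print(f"total BIC: { {m: round(b) for m, b in summary.total_bic.items()} }")
print(f"N best fit: {summary.n_best_fit}")
```

prints

```
prior mass     theta_1(83) = 0.007
likelihood     Pr(20c, 50% | r in bin 83) = 0.026
posterior mass theta_2(83) = 0.013
entropy drop   I = 0.550 bits (H: 7.209 -> 6.660)
sigma-hat: [14.04, 12.68, 13.65, 11.69]
total BIC: {'unbiased_updating': 5452, 'wsls': 5684}
N best fit: {'unbiased_updating': 4, 'wsls': 0}
```

Reading the output: a single 20-cent feedback after choosing 50% contrast
nearly doubles the belief (0.007 → 0.013) that the target sits near 60.2%,
resolving 0.55 bits of uncertainty. Fitting four simulated Bayesian agents
(true σ = 13) recovers σ̂ ≈ 12–14, and BIC correctly prefers the grid
estimator over the WSLS heuristic for all four.

A `beliefgrid` command-line tool exposes the same stages
(`simulate`, `fit`, `variables`, `erp`, `regress`); see `beliefgrid --help`.

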
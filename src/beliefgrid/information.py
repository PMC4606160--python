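"""Information-theoretic belief variables: uncertainty, update size, surprise.

Per trial the grid estimator yields a prior belief (before feedback) and a
posterior belief (after feedback), from which four scalar regressors are
derived:

* ``H`` -- belief uncertainty: Shannon entropy of the prior, in bits.
* ``I`` -- belief update size as mutual information: the entropy drop from
  prior to posterior, in bits (negative when feedback broadens belief).
* ``I_KL`` -- belief update size as Bayesian surprise: the Kullback-Leibler
  divergence KL(prior || posterior), in nats. Note the argument order: this
  follows the printed definition, which is the reverse of some conventions.
* ``S`` -- feedback surprise: the self-information, in bits, of the observed
  cent value under the prior predictive distribution over all possible
  feedback values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import entropy as _shannon

from .beliefs import BeliefState, bayes_update, init_prior, response_weights, _consistency_tables
from .task import DEFAULT_MAPPING, ContrastGrid, RewardMapping, _validate_feedback

__all__ = [
    "entropy",
    "update_size_mi",
    "update_size_kl",
    "feedback_predictive",
    "surprise",
    "belief_trajectory",
]


def entropy(belief: BeliefState) -> float:
    """Shannon entropy of the belief PMF, in bits (0 log 0 := 0)."""
    return float(_shannon(belief.pmf, base=2))


def _check_aligned(prior: BeliefState, posterior: BeliefState) -> None:
    if prior.grid._key() != posterior.grid._key():
        raise ValueError("prior and posterior are defined on different grids")


def update_size_mi(prior: BeliefState, posterior: BeliefState) -> float:
    """Entropy difference H(prior) - H(posterior), in bits."""
    _check_aligned(prior, posterior)
    return entropy(prior) - entropy(posterior)


def update_size_kl(prior: BeliefState, posterior: BeliefState) -> float:
    """KL(prior || posterior) in nats; +inf if the posterior lost support.

    Bins where the prior is zero contribute nothing; a bin with positive
    prior but zero posterior makes the divergence infinite, which is
    reported as ``inf`` rather than raised.
    """
    _check_aligned(prior, posterior)
    return float(rel_entr(prior.pmf, posterior.pmf).sum())


def feedback_predictive(belief: BeliefState, x_true: float, sigma: float,
                        mapping: RewardMapping = DEFAULT_MAPPING) -> np.ndarray:
    """Prior predictive PMF over all whole-cent feedback values 0..height.

    Marginalizes the feedback likelihood over the belief; with the grid's
    renormalized response weights the raw values already sum to one, the
    explicit normalization only guards the degenerate sigma = 0 corner.
    """
    w = response_weights(belief.grid, x_true, sigma)
    lik_all = _consistency_tables(belief.grid, mapping) @ w  # (height+1, J)
    pred = lik_all @ belief.pmf
    total = pred.sum()
    if total <= 0:
        raise ValueError("belief assigns zero probability to every feedback value")
    return pred / total


def surprise(belief: BeliefState, f: int, x_true: float, sigma: float,
             mapping: RewardMapping = DEFAULT_MAPPING) -> float:
    """Self-information -log2 Pr(f | x, belief), in bits; inf if Pr = 0."""
    f = _validate_feedback(f, mapping)
    p = feedback_predictive(belief, x_true, sigma, mapping)[f]
    if p <= 0.0:
        return float("inf")
    return float(-np.log2(p))


def belief_trajectory(trials: pd.DataFrame, sigma: float,
                      grid: ContrastGrid | None = None,
                      mapping: RewardMapping = DEFAULT_MAPPING,
                      likelihood_floor: float = 0.0) -> pd.DataFrame:
    """Run the grid estimator over a trial table and derive per-trial variables.

    ``trials`` needs columns ``block``, ``trial``, ``chosen`` and
    ``feedback`` (one participant, blocks in presentation order; beliefs are
    re-initialized to uniform at each block start). Returns one row per
    trial with columns ``block``, ``trial``, ``H_prior``, ``H_posterior``,
    ``I``, ``I_KL`` and ``S``.
    """
    from .task import DEFAULT_GRID

    grid = grid or DEFAULT_GRID
    rows = []
    for block, tab in trials.groupby("block", sort=False):
        belief = init_prior(grid)
        for row in tab.itertuples(index=False):
            f = int(row.feedback)
            post = bayes_update(belief, f, row.chosen, sigma, mapping,
                                likelihood_floor=likelihood_floor)
            rows.append({
                "block": block,
                "trial": row.trial,
                "H_prior": entropy(belief),
                "H_posterior": entropy(post),
                "I": update_size_mi(belief, post),
                "I_KL": update_size_kl(belief, post),
                "S": surprise(belief, f, row.chosen, sigma, mapping),
            })
            belief = post
    return pd.DataFrame(rows)
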
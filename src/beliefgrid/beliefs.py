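"""Bayesian grid estimator of target-contrast beliefs, and the WSLS heuristic.

Beliefs about the hidden target contrast are a probability mass function
theta_t over the bins of a :class:`~beliefgrid.task.ContrastGrid`. After
each trial the belief is updated by Bayes' rule with a likelihood that
marginalizes over *response uncertainty*: the chooser does not know exactly
which contrast they stopped the sweep at, so each candidate chosen contrast
is weighted by a zero-mean Gaussian (SD ``sigma``, in % contrast) of its
distance from the true chosen contrast. The same ``sigma`` blurs beliefs
into choice probabilities (belief PMF convolved with the Gaussian kernel).

Discretization convention: the Gaussian response weights are taken as
Gaussian mass per bin (density at the bin center times the effective bin
width) renormalized over the grid, so that they form a proper PMF over
candidate bins despite truncation at the grid bounds. This convention also
makes the prior predictive over feedback values sum to one exactly.

The win-stay/lose-shift (WSLS) heuristic keeps no belief distribution:
after a rewarded trial the choice PMF is the response-uncertainty Gaussian
centered on the previous choice; after an unrewarded trial (or at a block
start) it is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .task import (
    DEFAULT_MAPPING,
    ContrastGrid,
    RewardMapping,
    _validate_feedback,
    reward,
)

__all__ = [
    "BeliefState",
    "DegenerateUpdateError",
    "init_prior",
    "response_weights",
    "feedback_likelihood",
    "bayes_update",
    "choice_pmf",
    "wsls_choice_pmf",
]

_NORM_TOL = 1e-10


class DegenerateUpdateError(RuntimeError):
    """Raised when the marginal likelihood of an update is zero.

    Can only happen at sigma = 0, where the likelihood has point support
    and the observed feedback may be inconsistent with every bin.
    """


@dataclass(frozen=True)
class BeliefState:
    """A PMF over contrast bins representing belief about the target."""

    grid: ContrastGrid
    pmf: np.ndarray
    trial_index: int = 0

    def __post_init__(self):
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.shape != (self.grid.J,):
            raise ValueError(f"pmf length {pmf.shape} does not match grid J={self.grid.J}")
        if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > _NORM_TOL:
            raise ValueError("pmf entries must be >= 0 and sum to 1")
        pmf.setflags(write=False)
        object.__setattr__(self, "pmf", pmf)


def init_prior(grid: ContrastGrid) -> BeliefState:
    """Uniform belief over all bins (maximum-entropy block start)."""
    return BeliefState(grid=grid, pmf=np.full(grid.J, 1.0 / grid.J), trial_index=0)


def _gaussian_mass(distances: np.ndarray, sigma: float, width: float) -> np.ndarray:
    z = distances / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi)) * width


def response_weights(grid: ContrastGrid, x_true: float, sigma: float) -> np.ndarray:
    """Subjective probability that each bin was the actually chosen contrast.

    Gaussian mass per bin centered on ``x_true``, renormalized over the grid
    (truncation correction). At sigma = 0 this degenerates to a one-hot
    indicator of the bin containing ``x_true``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        w = np.zeros(grid.J)
        w[grid.bin_index(x_true)] = 1.0
        return w
    w = _gaussian_mass(grid.centers - x_true, sigma, grid.effective_width)
    return w / w.sum()


_TABLE_CACHE: dict[tuple, np.ndarray] = {}


def _consistency_tables(grid: ContrastGrid, mapping: RewardMapping) -> np.ndarray:
    """(height+1, J, J) array: table[f, j, j*] = 1 iff R(center_j, center_j*) = f.

    Cached per (grid, mapping); rewards depend only on |center_j - center_j*|
    so the tables are symmetric Toeplitz, but at J = 148 the dense form is
    small and keeps the likelihood a single matvec.
    """
    key = grid._key() + mapping._key()
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        c = grid.centers
        r = reward(c[:, None], c[None, :], mapping)  # (J, J) ints
        tab = np.stack([(r == f).astype(float) for f in range(mapping.height + 1)])
        _TABLE_CACHE[key] = tab
    return tab


def feedback_likelihood(grid: ContrastGrid, f: int, x_true: float, sigma: float,
                        mapping: RewardMapping = DEFAULT_MAPPING) -> np.ndarray:
    """Likelihood of (feedback f, choice x_true) for a target in each bin.

    Marginalizes the feedback-consistency indicator over all candidate
    chosen contrasts, weighted by the response-uncertainty Gaussian.
    """
    f = _validate_feedback(f, mapping)
    w = response_weights(grid, x_true, sigma)
    return _consistency_tables(grid, mapping)[f] @ w


def bayes_update(belief: BeliefState, f: int, x_true: float, sigma: float,
                 mapping: RewardMapping = DEFAULT_MAPPING,
                 likelihood_floor: float = 0.0) -> BeliefState:
    """One Bayes step: posterior ∝ prior × feedback likelihood.

    ``likelihood_floor`` > 0 (used during model fitting) keeps the update
    proper when sigma = 0 makes some bins exactly impossible; with the
    default floor of 0 an all-zero marginal raises
    :class:`DegenerateUpdateError`.
    """
    lik = feedback_likelihood(belief.grid, f, x_true, sigma, mapping)
    if likelihood_floor > 0:
        lik = np.maximum(lik, likelihood_floor)
    marginal = float(belief.pmf @ lik)
    if marginal <= 0.0:
        raise DegenerateUpdateError(
            f"feedback {f} at x={x_true} with sigma={sigma} has zero marginal likelihood"
        )
    return replace(belief, pmf=belief.pmf * lik / marginal,
                   trial_index=belief.trial_index + 1)


def _choice_kernel(grid: ContrastGrid, sigma: float) -> np.ndarray:
    """Gaussian mass kernel over signed bin offsets -(J-1) .. (J-1)."""
    offsets = np.arange(-(grid.J - 1), grid.J) * grid.effective_width
    return _gaussian_mass(offsets, sigma, grid.effective_width)


def choice_pmf(belief: BeliefState, sigma: float) -> np.ndarray:
    """Choice probabilities: belief blurred by the response-uncertainty kernel.

    Discrete convolution truncated at the grid bounds and renormalized (the
    normalization constant absorbs the truncated tails); sigma = 0 returns
    the belief PMF itself.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return np.array(belief.pmf)
    J = belief.grid.J
    conv = np.convolve(belief.pmf, _choice_kernel(belief.grid, sigma))[J - 1:2 * J - 1]
    return conv / conv.sum()


def wsls_choice_pmf(grid: ContrastGrid, prev_choice: float | None,
                    prev_feedback: int | None, sigma: float) -> np.ndarray:
    """Win-stay/lose-shift choice probabilities.

    Win (previous feedback > 0): response-uncertainty Gaussian centered on
    the previously chosen bin. Loss, or block start (``prev_feedback`` is
    None): uniform over the grid.
    """
    if prev_feedback is not None and prev_feedback > 0:
        if prev_choice is None:
            raise ValueError("previous choice required when previous feedback > 0")
        # Dirac at the previous chosen bin convolved with the Gaussian kernel
        # == response weights centered on that bin's center.
        center = grid.centers[grid.bin_index(prev_choice)]
        return response_weights(grid, center, sigma)
    return np.full(grid.J, 1.0 / grid.J)
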
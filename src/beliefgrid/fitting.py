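"""Maximum-likelihood fitting of the response-uncertainty parameter sigma.

Both behavioral models have a single free parameter per participant: the
SD sigma of the Gaussian response uncertainty. For a trial sequence the
negative log-likelihood sums -ln Pr(chosen bin) over trials, where the
choice PMF is the belief blurred by the sigma-kernel (grid estimator) or
the WSLS rule. Beliefs restart uniform at every block boundary; a small
likelihood floor keeps the sequential updates proper at extreme parameter
values. Models are compared per participant by BIC = k ln(n) - 2 lnL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .beliefs import _choice_kernel, _consistency_tables, response_weights
from .task import DEFAULT_GRID, DEFAULT_MAPPING, ContrastGrid, RewardMapping

__all__ = [
    "FitResult",
    "ComparisonSummary",
    "nll_updating",
    "nll_wsls",
    "fit_sigma",
    "compare_models",
]

MODELS = ("unbiased_updating", "wsls")
LIKELIHOOD_FLOOR = 1e-12
DEFAULT_BOUNDS = (0.1, 50.0)
BIC_TIE_TOL = 0.01


@dataclass(frozen=True)
class FitResult:
    participant_id: str | int
    model_name: str
    sigma_hat: float
    log_likelihood: float
    n_trials: int
    n_params: int = 1
    at_bound: bool = False

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2.0 * self.log_likelihood


@dataclass
class ComparisonSummary:
    """Cohort-level model comparison: totals plus per-participant BIC votes."""

    models: tuple[str, ...]
    total_log_likelihood: dict[str, float]
    total_bic: dict[str, float]
    n_best_fit: dict[str, int]
    n_ties: int
    n_participants: int
    per_participant: pd.DataFrame = field(repr=False)


def _response_weight_rows(grid: ContrastGrid, xs: np.ndarray, sigma: float) -> np.ndarray:
    """Vectorized response weights for many chosen contrasts (rows sum to 1)."""
    if sigma == 0.0:
        rows = np.zeros((len(xs), grid.J))
        rows[np.arange(len(xs)), grid.bin_index(xs)] = 1.0
        return rows
    z = (grid.centers[None, :] - np.asarray(xs, dtype=float)[:, None]) / sigma
    rows = np.exp(-0.5 * z * z)
    return rows / rows.sum(axis=1, keepdims=True)


def _require_trial_columns(trials: pd.DataFrame) -> None:
    missing = {"block", "chosen", "feedback"} - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")


def nll_updating(trials: pd.DataFrame, sigma: float,
                 grid: ContrastGrid = DEFAULT_GRID,
                 mapping: RewardMapping = DEFAULT_MAPPING) -> float:
    """Negative log-likelihood of choices under the grid-updating model.

    Sequential: each block starts from a uniform belief, each trial's choice
    probability is read from the blurred belief at the chosen bin, and the
    belief is then updated with the observed feedback.
    """
    _require_trial_columns(trials)
    J = grid.J
    tables = _consistency_tables(grid, mapping)
    kern = _choice_kernel(grid, sigma) if sigma > 0 else None
    chosen_bins = grid.bin_index(trials["chosen"].to_numpy())
    weight_rows = _response_weight_rows(grid, trials["chosen"].to_numpy(), sigma)
    feedbacks = trials["feedback"].to_numpy().astype(int)
    blocks = trials["block"].to_numpy()

    nll = 0.0
    theta = None
    prev_block = None
    for i in range(len(trials)):
        if blocks[i] != prev_block:
            theta = np.full(J, 1.0 / J)
            prev_block = blocks[i]
        if kern is None:
            cp = theta
        else:
            cp = np.convolve(theta, kern)[J - 1:2 * J - 1]
            cp = cp / cp.sum()
        nll -= np.log(max(cp[chosen_bins[i]], LIKELIHOOD_FLOOR))
        lik = np.maximum(tables[feedbacks[i]] @ weight_rows[i], LIKELIHOOD_FLOOR)
        theta = theta * lik
        theta /= theta.sum()
    return float(nll)


def nll_wsls(trials: pd.DataFrame, sigma: float,
             grid: ContrastGrid = DEFAULT_GRID,
             mapping: RewardMapping = DEFAULT_MAPPING) -> float:
    """Negative log-likelihood of choices under win-stay/lose-shift."""
    _require_trial_columns(trials)
    J = grid.J
    log_uniform = -np.log(J)
    chosen_bins = grid.bin_index(trials["chosen"].to_numpy())
    centers = grid.centers
    feedbacks = trials["feedback"].to_numpy().astype(int)
    blocks = trials["block"].to_numpy()

    nll = 0.0
    prev_block = None
    prev_bin = None
    prev_f = None
    for i in range(len(trials)):
        if blocks[i] != prev_block:
            prev_bin, prev_f = None, None
            prev_block = blocks[i]
        if prev_f is not None and prev_f > 0:
            pmf = response_weights(grid, centers[prev_bin], sigma)
            nll -= np.log(max(pmf[chosen_bins[i]], LIKELIHOOD_FLOOR))
        else:
            nll -= log_uniform
        prev_bin, prev_f = chosen_bins[i], feedbacks[i]
    return float(nll)


_NLL_FUNCS = {"unbiased_updating": nll_updating, "wsls": nll_wsls}


def fit_sigma(trials: pd.DataFrame, model_name: str,
              bounds: tuple[float, float] = DEFAULT_BOUNDS,
              n_starts: int = 3, seed: int = 0,
              grid: ContrastGrid = DEFAULT_GRID,
              mapping: RewardMapping = DEFAULT_MAPPING,
              participant_id: str | int = 0) -> FitResult:
    """Bounded ML estimate of sigma with multi-start scalar optimization.

    The sigma range is split into ``n_starts`` subintervals at seeded random
    breakpoints and each is searched with derivative-free bounded Brent
    minimization (xatol 1e-6); the best optimum wins, ties broken toward
    smaller sigma. Deterministic for a given seed. ``at_bound`` flags
    optima pinned to a search bound.
    """
    if model_name not in _NLL_FUNCS:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODELS}")
    nll = _NLL_FUNCS[model_name]
    lo, hi = bounds
    rng = np.random.default_rng(seed)
    interior = np.sort(rng.uniform(lo, hi, max(0, n_starts - 1)))
    breaks = np.concatenate([[lo], interior, [hi]])

    best = None
    any_success = False
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a < 1e-4:
            continue
        res = minimize_scalar(lambda s: nll(trials, float(s), grid, mapping),
                              bounds=(a, b), method="bounded",
                              options={"xatol": 1e-6})
        any_success = any_success or bool(res.success)
        cand = (float(res.fun), float(res.x))
        if best is None or cand < best:
            best = cand
    if not any_success:
        raise RuntimeError(f"sigma optimization failed to converge on all {n_starts} starts")
    fun, sig = best
    return FitResult(
        participant_id=participant_id,
        model_name=model_name,
        sigma_hat=sig,
        log_likelihood=-fun,
        n_trials=int(len(trials)),
        at_bound=bool(min(sig - lo, hi - sig) < 1e-6 * (hi - lo)),
    )


def compare_models(fits: list[FitResult]) -> ComparisonSummary:
    """Summarize per-participant fits of both models into a BIC comparison.

    ``n_best_fit`` counts participants whose BIC favors each model;
    participants with |BIC difference| < 0.01 are counted as ties and
    reported separately. Every participant must have one fit per model.
    """
    models = tuple(sorted({f.model_name for f in fits}))
    by_pid: dict = {}
    for f in fits:
        by_pid.setdefault(f.participant_id, {})[f.model_name] = f
    for pid, d in by_pid.items():
        if set(d) != set(models):
            raise ValueError(f"participant {pid!r} missing fits for {set(models) - set(d)}")

    rows = []
    n_best = {m: 0 for m in models}
    n_ties = 0
    for pid, d in by_pid.items():
        bics = {m: d[m].bic for m in models}
        ordered = sorted(bics, key=bics.get)
        if len(models) > 1 and bics[ordered[1]] - bics[ordered[0]] < BIC_TIE_TOL:
            n_ties += 1
            winner = None
        else:
            winner = ordered[0]
            n_best[winner] += 1
        rows.append({"participant_id": pid, "best_model": winner,
                     **{f"bic_{m}": bics[m] for m in models},
                     **{f"sigma_{m}": d[m].sigma_hat for m in models}})

    return ComparisonSummary(
        models=models,
        total_log_likelihood={m: sum(d[m].log_likelihood for d in by_pid.values()) for m in models},
        total_bic={m: sum(d[m].bic for d in by_pid.values()) for m in models},
        n_best_fit=n_best,
        n_ties=n_ties,
        n_participants=len(by_pid),
        per_participant=pd.DataFrame(rows),
    )
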
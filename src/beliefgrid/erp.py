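"""Single-trial ERP amplitude extraction and robust regression analysis.

Amplitudes are read from feedback-locked epochs with the standard window
conventions: the P3 is the post-feedback maximum in 300-450 ms after
baseline correction to the mean of the 200 ms immediately pre-feedback;
the SPN is the mean of the last 500 ms before feedback, baseline-corrected
to the mean of -1500 to -1300 ms.

Statistics follow the single-trial model-based ERP approach: amplitudes
are z-normalized within participant, predictors standardized, and each
participant x electrode regression is fitted by iteratively reweighted
least squares with the bisquare (Tukey biweight) influence function,
tuning constant 4.685. Participant-level betas are then tested against
zero with Bonferroni-corrected one-sample t tests across the electrode
family (4 midline electrodes for the P3, 10 bilateral electrodes for the
SPN). A 3 (trial stage) x 2 (median-split update size) repeated-measures
ANOVA on per-participant cell means serves as the trial-number control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .simulate import P3_ELECTRODES, SPN_ELECTRODES, EpochSet

__all__ = [
    "P3_ELECTRODES",
    "SPN_ELECTRODES",
    "RegressionResult",
    "AnovaResult",
    "extract_p3",
    "extract_spn",
    "extract_amplitudes",
    "znormalize",
    "robust_regress",
    "group_test",
    "single_trial_regression",
    "factorial_control",
]

BISQUARE_TUNING = 4.685

P3_WINDOW_MS = (300.0, 450.0)
P3_BASELINE_MS = (-200.0, 0.0)
SPN_WINDOW_MS = (-500.0, 0.0)
SPN_BASELINE_MS = (-1500.0, -1300.0)

P3_PREDICTORS = ("feedback", "I", "S")
SPN_PREDICTORS = ("H_prior",)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"window {window} ms outside epoch time axis "
                         f"[{times[0]}, {times[-1]}] ms")
    return (times >= lo) & (times <= hi)


def extract_p3(epochs: EpochSet, electrode: str) -> np.ndarray:
    """Per-trial P3: max over 300-450 ms minus the -200..0 ms baseline mean."""
    ch = epochs.electrode_index(electrode)
    sig = epochs.data[:, ch, :].astype(float)
    base = sig[:, _window_mask(epochs.times_ms, P3_BASELINE_MS)].mean(axis=1)
    peak = sig[:, _window_mask(epochs.times_ms, P3_WINDOW_MS)].max(axis=1)
    return peak - base


def extract_spn(epochs: EpochSet, electrode: str) -> np.ndarray:
    """Per-trial SPN: mean over -500..0 ms minus the -1500..-1300 ms baseline."""
    ch = epochs.electrode_index(electrode)
    sig = epochs.data[:, ch, :].astype(float)
    base = sig[:, _window_mask(epochs.times_ms, SPN_BASELINE_MS)].mean(axis=1)
    win = sig[:, _window_mask(epochs.times_ms, SPN_WINDOW_MS)].mean(axis=1)
    return win - base


_EXTRACTORS = {"p3": extract_p3, "spn": extract_spn}


def extract_amplitudes(epochs: EpochSet, component: str,
                       electrodes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Long-format amplitude table: one row per (trial, electrode)."""
    if component not in _EXTRACTORS:
        raise ValueError(f"component must be 'p3' or 'spn', got {component!r}")
    electrodes = electrodes or (P3_ELECTRODES if component == "p3" else SPN_ELECTRODES)
    frames = []
    for el in electrodes:
        tab = epochs.meta.copy()
        tab["electrode"] = el
        tab["amplitude"] = _EXTRACTORS[component](epochs, el)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def znormalize(values: np.ndarray, participants: np.ndarray) -> np.ndarray:
    """Within-participant z scores (mean 0, SD 1 per participant)."""
    values = np.asarray(values, dtype=float)
    participants = np.asarray(participants)
    out = np.empty_like(values)
    for pid in np.unique(participants):
        m = participants == pid
        if m.sum() < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 trials")
        sd = values[m].std(ddof=0)
        if sd == 0:
            raise ValueError(f"participant {pid!r} has zero amplitude variance")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def _irls_batch(Y: np.ndarray, X: np.ndarray, max_iter: int = 50,
                tol: float = 1e-8, tuning: float = BISQUARE_TUNING) -> np.ndarray:
    """Bisquare IRLS for m independent regressions sharing a design matrix.

    Y: (m, n) responses; X: (n, p) design (intercept included by caller).
    Scale is re-estimated each iteration from the residual MAD. Returns
    (m, p) coefficients.
    """
    m, n = Y.shape
    p = X.shape[1]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ Y.T).T  # OLS start, (m, p)
    for _ in range(max_iter):
        resid = Y - beta @ X.T  # (m, n)
        # MAD about zero (residuals already include the intercept), the
        # convention of standard robust-regression implementations.
        scale = np.median(np.abs(resid), axis=1, keepdims=True) / 0.6745
        scale = np.where(scale <= 0, np.maximum(np.abs(resid).max(axis=1, keepdims=True), 1e-12),
                         scale)
        u = resid / (tuning * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)  # (m, n)
        degenerate = (w > 0).sum(axis=1) < p  # all mass rejected; fall back to OLS step
        if np.any(degenerate):
            w[degenerate] = 1.0
        # Weighted normal equations per problem: (X' W X) b = X' W y.
        Xw = w[:, :, None] * X[None, :, :]  # (m, n, p)
        A = np.einsum("np,mnq->mpq", X, Xw)
        b = np.einsum("mnp,mn->mp", Xw, Y)
        new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    return beta


def robust_regress(y: np.ndarray, X: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8) -> np.ndarray:
    """Robust (bisquare IRLS) linear regression of y on X with an intercept.

    Returns the coefficient vector with the intercept first. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations for {p} predictors, got {n}")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear predictor "
                         f"column(s): {bad}")
    return _irls_batch(y[None, :], design, max_iter=max_iter, tol=tol)[0]


def _collinear_columns(X: np.ndarray) -> list[int]:
    bad = [j for j in range(X.shape[1]) if np.allclose(X[:, j], X[:, j].mean())]
    if not bad:
        corr = np.corrcoef(X, rowvar=False)
        iu = zip(*np.triu_indices_from(np.atleast_2d(corr), k=1))
        bad = sorted({j for i, j in iu if abs(corr[i, j]) > 1 - 1e-10})
    return bad


@dataclass
class RegressionResult:
    """Group-level outcome of a single-trial regression family."""

    component: str
    predictors: tuple[str, ...]
    electrodes: tuple[str, ...]
    n_comparisons: int
    betas: pd.DataFrame  # one row per participant x electrode
    group: pd.DataFrame  # one row per electrode x predictor


def group_test(betas: pd.DataFrame, n_comparisons: int,
               alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-corrected one-sample t tests of betas against zero.

    ``betas``: rows = participants, one column per predictor (a single
    electrode's family member). Degenerate all-equal betas give t = NaN and
    are reported non-significant.
    """
    if len(betas) < 3:
        raise ValueError("group test requires at least 3 participants")
    rows = []
    for col in betas.columns:
        vals = betas[col].to_numpy(dtype=float)
        if np.allclose(vals.std(ddof=1), 0.0):
            t, p = float("nan"), 1.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        p_corr = min(1.0, float(p) * n_comparisons)
        rows.append({"predictor": col, "mean_beta": vals.mean(), "t": float(t),
                     "df": len(vals) - 1, "p_corrected": p_corr,
                     "significant": bool(p_corr < alpha)})
    return pd.DataFrame(rows)


def single_trial_regression(amplitudes: pd.DataFrame, variables: pd.DataFrame,
                            predictors: tuple[str, ...],
                            component: str = "p3",
                            electrodes: tuple[str, ...] | None = None,
                            n_comparisons: int | None = None,
                            alpha: float = 0.05) -> RegressionResult:
    """Per-participant robust regressions plus group-level Bonferroni tests.

    ``amplitudes`` is the long table from :func:`extract_amplitudes`;
    ``variables`` carries per-trial predictors keyed by (participant,
    block, trial). Amplitudes are z-normalized and predictors standardized
    within participant. The two update-size formulations I and I_KL are
    never admitted together (they measure the same construct).
    """
    if "I" in predictors and "I_KL" in predictors:
        raise ValueError("include either I or I_KL as the update-size measure, never both")
    merged = amplitudes.merge(variables, on=["participant", "block", "trial"],
                              validate="many_to_one")
    electrodes = tuple(electrodes or sorted(merged["electrode"].unique()))
    if n_comparisons is None:
        n_comparisons = len(electrodes)

    beta_rows = []
    for (el, pid), tab in merged.groupby(["electrode", "participant"]):
        if el not in electrodes:
            continue
        y = znormalize(tab["amplitude"].to_numpy(), np.zeros(len(tab)))
        X = np.column_stack([
            znormalize(tab[p].to_numpy(dtype=float), np.zeros(len(tab)))
            for p in predictors
        ])
        coefs = robust_regress(y, X)
        beta_rows.append({"electrode": el, "participant": pid,
                          **{p: coefs[k + 1] for k, p in enumerate(predictors)}})
    betas = pd.DataFrame(beta_rows)

    group_frames = []
    for el in electrodes:
        sub = betas[betas["electrode"] == el].set_index("participant")[list(predictors)]
        g = group_test(sub, n_comparisons, alpha=alpha)
        g.insert(0, "electrode", el)
        group_frames.append(g)
    return RegressionResult(component=component, predictors=tuple(predictors),
                            electrodes=electrodes, n_comparisons=n_comparisons,
                            betas=betas, group=pd.concat(group_frames, ignore_index=True))


@dataclass
class AnovaResult:
    """3 (stage) x 2 (update size) repeated-measures ANOVA outcome."""

    table: pd.DataFrame  # F, num/den df, p per effect
    cell_stats: pd.DataFrame  # mean and SD of cell means across participants
    cell_means: pd.DataFrame  # per participant x stage x size


_STAGES = {"early": (1, 5), "middle": (6, 10), "late": (11, 15)}


def factorial_control(amplitudes: pd.DataFrame, variables: pd.DataFrame) -> AnovaResult:
    """Trial-number control: stage x median-split update size ANOVA.

    Trials 1-15 are partitioned into early/middle/late stages; within each
    participant, trials are split at the participant's median update size
    I. Cell means are computed per participant first and fed to a
    repeated-measures ANOVA. Raises if any participant has an empty cell.
    """
    merged = amplitudes.merge(variables, on=["participant", "block", "trial"],
                              validate="many_to_one")
    merged = merged[merged["trial"].between(1, 15)].copy()
    if merged.empty:
        raise ValueError("no trials in range 1-15")
    merged["stage"] = pd.cut(merged["trial"], bins=[0, 5, 10, 15],
                             labels=list(_STAGES)).astype(str)
    merged["update_size"] = (
        merged.groupby("participant")["I"]
        .transform(lambda v: np.where(v > v.median(), "large", "small"))
    )

    cells = (merged.groupby(["participant", "stage", "update_size"], sort=True)
             ["amplitude"].mean().reset_index())
    counts = cells.groupby("participant").size()
    incomplete = counts[counts < 6].index.tolist()
    if incomplete:
        raise ValueError(f"participants with empty stage x update-size cells: {incomplete}")

    fit = AnovaRM(cells, depvar="amplitude", subject="participant",
                  within=["update_size", "stage"]).fit()
    table = fit.anova_table.rename(columns={"F Value": "F", "Num DF": "df_num",
                                            "Den DF": "df_den", "Pr > F": "p"})
    stats_tab = (cells.groupby(["stage", "update_size"])["amplitude"]
                 .agg(["mean", "std"]).reset_index())
    return AnovaResult(table=table, cell_stats=stats_tab, cell_means=cells)
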
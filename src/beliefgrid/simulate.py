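"""Synthetic agents and synthetic single-trial EEG epochs.

Behavioral side: simulated participants play the contrast-reward task with
one of three choice policies -- a Bayesian grid updater (choices sampled
from the blurred belief), a WSLS heuristic, or a uniform-random chooser.
Targets are drawn uniformly on [25, 85]% contrast; each block runs until 25
trials or 180 s of cumulative stimulus presentation, whichever comes first.
Choices are sampled in contrast space; the response time of a trial is
back-computed as the first moment the sweeping stimulus reaches the chosen
contrast, which is all the block-duration rule needs.

EEG side: :func:`simulate_epochs` builds feedback-locked epochs (-1500 to
+1500 ms) with planted linear dependencies -- a P3-like Gaussian bump whose
peak tracks belief update size ``I`` at designated fronto-central sites,
and a pre-feedback negative ramp whose window mean tracks belief
uncertainty ``H`` (with a negative coefficient) at designated
central/parietal sites. Predictors are z-scored within participant so the
planted betas are in the normalized units the regression pipeline reports;
trial-to-trial amplitude variability is planted on the component statistic
(residual SD sqrt(1 - beta^2)) with white sensor noise on top, and all
other electrodes carry sensor noise only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beliefs import bayes_update, choice_pmf, init_prior, wsls_choice_pmf
from .task import (
    DEFAULT_GRID,
    DEFAULT_MAPPING,
    ContrastGrid,
    RewardMapping,
    TrajectoryParams,
    first_crossing_time,
    reward,
)

__all__ = [
    "AGENTS",
    "P3_ELECTRODES",
    "SPN_ELECTRODES",
    "ALL_ELECTRODES",
    "EffectSpec",
    "EpochSet",
    "simulate_participant",
    "simulate_cohort",
    "simulate_epochs",
    "save_epochs",
    "load_epochs",
]

AGENTS = ("bayesian", "wsls", "random")

# Electrode families used in the single-trial analyses (midline P3 row and
# the bilateral SPN montage).
P3_ELECTRODES = ("FCz", "Cz", "CPz", "Pz")
SPN_ELECTRODES = ("F3", "F4", "C3", "C4", "T7", "T8", "P3", "P4", "O1", "O2")
ALL_ELECTRODES = P3_ELECTRODES + SPN_ELECTRODES

TARGET_RANGE = (25.0, 85.0)
MAX_TRIALS_PER_BLOCK = 25
MAX_BLOCK_PRESENTATION_S = 180.0
HALF_CYCLES_S = (6.0, 7.0, 8.0, 9.0)


def simulate_participant(participant_id, agent: str = "bayesian", sigma: float = 13.0,
                         n_blocks: int = 15, seed: int = 0,
                         grid: ContrastGrid = DEFAULT_GRID,
                         mapping: RewardMapping = DEFAULT_MAPPING) -> pd.DataFrame:
    """Simulate one participant's trial table.

    The default sigma of 13% contrast sits at the cohort-typical level of
    response uncertainty; 15 blocks matches the session length of the task.
    Fully reproducible given ``seed``.
    """
    if agent not in AGENTS:
        raise ValueError(f"unknown agent {agent!r}; expected one of {AGENTS}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    centers = grid.centers
    rows = []
    for block in range(1, n_blocks + 1):
        target = rng.uniform(*TARGET_RANGE)
        belief = init_prior(grid) if agent == "bayesian" else None
        prev_choice, prev_feedback = None, None
        cum_s = 0.0
        trial = 0
        while trial < MAX_TRIALS_PER_BLOCK and cum_s <= MAX_BLOCK_PRESENTATION_S:
            trial += 1
            params = TrajectoryParams(
                initial_contrast=rng.uniform(grid.lower, grid.upper),
                initial_direction=rng.choice(("up", "down")),
                half_cycle_s=float(rng.choice(HALF_CYCLES_S)),
                bounds=(grid.lower, grid.upper),
            )
            if agent == "bayesian":
                pmf = choice_pmf(belief, sigma)
            elif agent == "wsls":
                pmf = wsls_choice_pmf(grid, prev_choice, prev_feedback, sigma)
            else:
                pmf = np.full(grid.J, 1.0 / grid.J)
            # Sample the choice in contrast space; re-sample in the (never
            # observed with in-grid bin centers) case of no sweep crossing.
            for _ in range(100):
                chosen = float(centers[rng.choice(grid.J, p=pmf)])
                rt = first_crossing_time(params, chosen)
                if rt is not None:
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("no trajectory crossing for any sampled choice")
            f = int(reward(target, chosen, mapping))
            rows.append({
                "participant": participant_id, "block": block, "trial": trial,
                "target": target, "chosen": chosen, "feedback": f,
                "init_contrast": params.initial_contrast,
                "init_direction": params.initial_direction,
                "half_cycle_s": params.half_cycle_s, "rt_s": rt,
            })
            if agent == "bayesian":
                belief = bayes_update(belief, f, chosen, sigma, mapping)
            prev_choice, prev_feedback = chosen, f
            cum_s += rt
    return pd.DataFrame(rows)


def simulate_cohort(n_participants: int = 16, agent: str = "bayesian",
                    sigma: float = 13.0, n_blocks: int = 15, seed: int = 0,
                    grid: ContrastGrid = DEFAULT_GRID,
                    mapping: RewardMapping = DEFAULT_MAPPING) -> pd.DataFrame:
    """Simulate a cohort (defaults mirror the 16-participant design scale)."""
    seeds = np.random.SeedSequence(seed).spawn(n_participants)
    frames = [
        simulate_participant(pid, agent=agent, sigma=sigma, n_blocks=n_blocks,
                             seed=child, grid=grid, mapping=mapping)
        for pid, child in enumerate(seeds, start=1)
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EffectSpec:
    """Planted single-trial effect sizes and epoch morphology.

    Betas are in z-units: amplitude SDs of the extracted component per SD of
    the (within-participant z-scored) predictor. ``beta_p3`` scales the P3
    bump peak with update size I; ``beta_spn`` scales the pre-feedback ramp
    mean with uncertainty H and is negative for the empirically observed
    direction. ``noise_sd`` is white sensor noise per sample (set
    ``ar_rho`` > 0 for AR(1) temporally correlated noise).
    """

    beta_p3: float = 0.27
    beta_spn: float = -0.06
    noise_sd: float = 0.2
    p3_latency_ms: float = 350.0
    p3_width_ms: float = 45.0  # Gaussian SD of the bump
    p3_baseline_amp: float = 5.0
    spn_baseline_amp: float = -1.0
    spn_ramp_shape: str = "linear"
    ar_rho: float = 0.0

    def __post_init__(self):
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 300.0 <= self.p3_latency_ms <= 450.0:
            raise ValueError("p3 latency must lie inside the 300-450 ms analysis window")
        if self.spn_ramp_shape != "linear":
            raise ValueError("only the linear SPN ramp shape is implemented")
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must be in [0, 1)")


@dataclass
class EpochSet:
    """Feedback-locked epochs: (n_trials, n_electrodes, n_times) voltages.

    ``times_ms`` is relative to feedback onset; ``meta`` has one row per
    epoch (participant, block, trial) aligned with the first axis.
    """

    data: np.ndarray
    times_ms: np.ndarray
    electrodes: tuple[str, ...]
    sfreq: float
    meta: pd.DataFrame

    def __post_init__(self):
        n_tr, n_el, n_t = self.data.shape
        if n_el != len(self.electrodes) or n_t != len(self.times_ms):
            raise ValueError("epoch array axes do not match electrode/time labels")
        if len(self.meta) != n_tr:
            raise ValueError("one metadata row per epoch required")

    def electrode_index(self, name: str) -> int:
        try:
            return self.electrodes.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in epoch set {self.electrodes}") from None


def _epoch_times(sfreq: float, t_min_ms: float = -1500.0, t_max_ms: float = 1500.0) -> np.ndarray:
    n = int(round((t_max_ms - t_min_ms) / 1000.0 * sfreq)) + 1
    return t_min_ms + np.arange(n) * 1000.0 / sfreq


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_epochs(trials_with_vars: pd.DataFrame, spec: EffectSpec = EffectSpec(),
                    electrodes: tuple[str, ...] = ALL_ELECTRODES,
                    p3_sites: tuple[str, ...] = ("FCz",),
                    spn_sites: tuple[str, ...] = ("C3", "P4"),
                    sfreq: float = 128.0, seed: int = 0) -> EpochSet:
    """Generate one epoch per trial with planted P3 / SPN dependencies.

    ``trials_with_vars`` needs ``participant``, ``block``, ``trial`` plus
    the model-derived ``I`` (for the P3 bump) and ``H_prior`` (for the SPN
    ramp). Signal + noise are separable: averaging epochs with identical
    predictor values converges on the planted waveform.
    """
    required = {"participant", "block", "trial", "I", "H_prior"}
    missing = required - set(trials_with_vars.columns)
    if missing:
        raise ValueError(f"trial table missing variable columns: {sorted(missing)}")
    unknown = (set(p3_sites) | set(spn_sites)) - set(electrodes)
    if unknown:
        raise ValueError(f"planted sites {sorted(unknown)} not in electrode list")

    rng = np.random.default_rng(seed)
    times = _epoch_times(sfreq)
    n_trials, n_el, n_t = len(trials_with_vars), len(electrodes), len(times)

    # Within-participant z-scored predictors.
    z_i = trials_with_vars.groupby("participant")["I"].transform(_zscore).to_numpy()
    z_h = trials_with_vars.groupby("participant")["H_prior"].transform(_zscore).to_numpy()

    data = rng.normal(0.0, spec.noise_sd, size=(n_trials, n_el, n_t))
    if spec.ar_rho > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_rho ** 2)
        data *= innov_sd / spec.noise_sd
        for k in range(1, n_t):
            data[:, :, k] += spec.ar_rho * data[:, :, k - 1]

    resid_p3 = np.sqrt(max(0.0, 1.0 - spec.beta_p3 ** 2))
    resid_spn = np.sqrt(max(0.0, 1.0 - spec.beta_spn ** 2))
    bump = np.exp(-0.5 * ((times - spec.p3_latency_ms) / spec.p3_width_ms) ** 2)
    # Ramp: 0 before -500 ms, linear to twice the target mean at feedback
    # onset (window mean over [-500, 0] therefore equals the target), then a
    # quick linear return to baseline.
    ramp = np.zeros(n_t)
    in_ramp = (times >= -500.0) & (times <= 0.0)
    ramp[in_ramp] = (times[in_ramp] + 500.0) / 500.0 * 2.0
    decay = (times > 0.0) & (times <= 200.0)
    ramp[decay] = 2.0 * (1.0 - times[decay] / 200.0)

    for site in p3_sites:
        amp = spec.p3_baseline_amp + spec.beta_p3 * z_i + resid_p3 * rng.normal(size=n_trials)
        data[:, electrodes.index(site), :] += amp[:, None] * bump[None, :]
    for site in spn_sites:
        amp = spec.spn_baseline_amp + spec.beta_spn * z_h + resid_spn * rng.normal(size=n_trials)
        data[:, electrodes.index(site), :] += amp[:, None] * ramp[None, :]

    meta = trials_with_vars[["participant", "block", "trial"]].reset_index(drop=True)
    return EpochSet(data=data.astype(np.float32), times_ms=times,
                    electrodes=tuple(electrodes), sfreq=float(sfreq), meta=meta)


def save_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.npy`` (float32 array) + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    sidecar = prefix.with_suffix(".json")
    np.save(npy, epochs.data)
    meta = {
        "electrodes": list(epochs.electrodes),
        "sfreq": epochs.sfreq,
        "t0_ms": float(epochs.times_ms[0]),
        "trials": {c: epochs.meta[c].tolist() for c in epochs.meta.columns},
    }
    sidecar.write_text(json.dumps(meta))
    return npy, sidecar


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    times = meta["t0_ms"] + np.arange(data.shape[2]) * 1000.0 / meta["sfreq"]
    return EpochSet(
        data=data, times_ms=times, electrodes=tuple(meta["electrodes"]),
        sfreq=float(meta["sfreq"]), meta=pd.DataFrame(meta["trials"]),
    )
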
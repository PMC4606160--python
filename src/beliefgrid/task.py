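"""Contrast space, reward mapping, and stimulus trajectories.

The task pairs a dynamic checkerboard whose contrast sweeps linearly back
and forth between two extremes with a hidden, maximally rewarding target
contrast. The participant stops the sweep to choose a contrast and earns a
whole-cent reward that falls off linearly with the distance between chosen
and target contrast (a symmetric triangular mapping). This module holds the
three static ingredients every other module builds on:

* :class:`ContrastGrid` -- the discretized contrast space on which beliefs
  are represented,
* :class:`RewardMapping` and :func:`reward` -- the triangular contrast-to-
  cents mapping,
* :class:`TrajectoryParams` and :func:`gen_trajectory` -- the piecewise
  linear, reflecting contrast path shown on screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ContrastGrid",
    "RewardMapping",
    "TrajectoryParams",
    "DEFAULT_GRID",
    "DEFAULT_MAPPING",
    "make_grid",
    "reward",
    "consistent_bins",
    "gen_trajectory",
    "load_task_config",
]


def _round_half_up(values):
    """Round to the nearest integer, ties away from zero-point-five upward.

    The tie rule for whole-cent feedback is isolated here so that the
    convention is stated (and changeable) in exactly one place.
    """
    return np.floor(np.asarray(values, dtype=float) + 0.5)


@dataclass(frozen=True)
class ContrastGrid:
    """Discretized contrast space: ``J`` equal bins tiling [lower, upper].

    ``width`` is the nominal bin width requested at construction; the
    effective width ``(upper - lower) / J`` is what actually tiles the
    interval, so bin centers are exact.
    """

    lower: float
    upper: float
    width: float
    J: int

    @property
    def effective_width(self) -> float:
        return (self.upper - self.lower) / self.J

    @cached_property
    def centers(self) -> np.ndarray:
        """Ordered bin centers, ``lower + (j - 0.5) * effective_width``."""
        c = self.lower + (np.arange(self.J) + 0.5) * self.effective_width
        c.setflags(write=False)
        return c

    @cached_property
    def edges(self) -> np.ndarray:
        e = self.lower + np.arange(self.J + 1) * self.effective_width
        e.setflags(write=False)
        return e

    def bin_index(self, x) -> np.ndarray | int:
        """Map contrast value(s) in [lower, upper] to 0-based bin indices."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lower) or np.any(x > self.upper):
            raise ValueError(
                f"contrast outside grid bounds [{self.lower}, {self.upper}]"
            )
        idx = np.floor((x - self.lower) / self.effective_width).astype(int)
        idx = np.clip(idx, 0, self.J - 1)
        return idx if idx.ndim else int(idx)

    def _key(self) -> tuple:
        return (self.lower, self.upper, self.J)


def make_grid(lower: float = 10.0, upper: float = 100.0, width: float = 0.61) -> ContrastGrid:
    """Build a contrast grid; ``J = ceil((upper - lower) / width)``.

    The default (10, 100, 0.61) yields the 148-bin space used for belief
    estimation; 0.61% is the largest width that still resolves adjacent
    whole-cent feedback values on the triangular mapping.
    """
    if not (upper > lower):
        raise ValueError(f"need upper > lower, got [{lower}, {upper}]")
    if not (width > 0):
        raise ValueError(f"need width > 0, got {width}")
    J = int(np.ceil((upper - lower) / width))
    return ContrastGrid(lower=float(lower), upper=float(upper), width=float(width), J=J)


@dataclass(frozen=True)
class RewardMapping:
    """Symmetric triangular contrast-difference -> cents mapping.

    ``height`` cents at zero difference, falling to zero at ``half_width``
    percent contrast difference (slope = height / half_width cents per %).
    """

    height: int = 25
    half_width: float = 15.0

    @property
    def slope(self) -> float:
        return self.height / self.half_width

    def _key(self) -> tuple:
        return (self.height, self.half_width)


DEFAULT_GRID = make_grid()
DEFAULT_MAPPING = RewardMapping()


def reward(r, x, mapping: RewardMapping = DEFAULT_MAPPING):
    """Whole-cent reward for chosen contrast ``x`` given target ``r``.

    ``round(height - slope * |r - x|)`` inside the triangle, 0 outside.
    Symmetric in its first two arguments; accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(x))):
        raise ValueError("contrasts must be finite")
    d = np.abs(r - x)
    cents = np.where(d < mapping.half_width,
                     _round_half_up(mapping.height - mapping.slope * d), 0.0)
    cents = cents.astype(int)
    return cents if cents.ndim else int(cents)


def consistent_bins(grid: ContrastGrid, f: int, x_candidate: float,
                    mapping: RewardMapping = DEFAULT_MAPPING) -> np.ndarray:
    """Indicator over target bins logically consistent with feedback ``f``.

    Entry ``j`` is 1 iff a target at the center of bin ``j`` would produce
    exactly ``f`` cents for a choice at ``x_candidate``.
    """
    f = _validate_feedback(f, mapping)
    return (reward(grid.centers, x_candidate, mapping) == f).astype(np.int8)


def _validate_feedback(f, mapping: RewardMapping) -> int:
    fi = int(f)
    if fi != f or not (0 <= fi <= mapping.height):
        raise ValueError(f"feedback must be an integer in [0, {mapping.height}], got {f}")
    return fi


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of one trial's reflecting linear contrast sweep."""

    initial_contrast: float
    initial_direction: str  # "up" | "down"
    half_cycle_s: float  # seconds for a full lower->upper sweep
    bounds: tuple[float, float] = (10.0, 100.0)

    _HALF_CYCLES = (6.0, 7.0, 8.0, 9.0)

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo <= self.initial_contrast <= hi:
            raise ValueError(
                f"initial contrast {self.initial_contrast} outside bounds {self.bounds}"
            )
        if self.initial_direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.initial_direction!r}")
        if float(self.half_cycle_s) not in self._HALF_CYCLES:
            raise ValueError(f"half-cycle period must be one of {self._HALF_CYCLES} s")


def _triangle_path(params: TrajectoryParams, t: np.ndarray) -> np.ndarray:
    # Unfold the reflecting path into a straight line, then fold back with a
    # triangular map; exact (no accumulation of reflection error).
    lo, hi = params.bounds
    span = hi - lo
    speed = span / params.half_cycle_s
    sign = 1.0 if params.initial_direction == "up" else -1.0
    unfolded = (params.initial_contrast - lo) + sign * speed * t
    y = np.mod(unfolded, 2.0 * span)
    return lo + np.where(y <= span, y, 2.0 * span - y)


def gen_trajectory(params: TrajectoryParams, duration_s: float = 30.0,
                   dt_s: float = 1.0 / 120.0) -> pd.DataFrame:
    """Sample the contrast path at ``dt_s`` resolution.

    Returns a two-column frame (``time_s``, ``contrast_pct``) ready for TSV
    export. The path is continuous and piecewise linear, reflecting at the
    grid bounds with constant absolute slope ``span / half_cycle_s``.
    """
    if not (0 < duration_s <= 30.0):
        raise ValueError("duration must be in (0, 30] s (maximum stimulus duration)")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    return pd.DataFrame({"time_s": t, "contrast_pct": _triangle_path(params, t)})


def first_crossing_time(params: TrajectoryParams, level: float,
                        duration_s: float = 30.0) -> float | None:
    """First time at which the sweep reaches ``level``, or None within duration.

    Solved on the unfolded line, so the answer is exact rather than sampled.
    """
    lo, hi = params.bounds
    if not lo <= level <= hi:
        raise ValueError(f"level {level} outside bounds {params.bounds}")
    span = hi - lo
    speed = span / params.half_cycle_s
    sign = 1.0 if params.initial_direction == "up" else -1.0
    p0 = params.initial_contrast - lo
    v = level - lo
    # path(t) = fold(p0 + sign*speed*t); fold(u) == v  iff  u ≡ ±v (mod 2*span)
    best = None
    for target in (v, -v):
        # sign*speed*t = target - p0 + 2*span*k  ->  smallest t >= 0
        delta = (target - p0) / (sign * speed)
        period = 2.0 * span / speed
        k = np.ceil(-delta / period)
        tcross = delta + k * period
        if tcross < 0:  # numerical guard
            tcross += period
        if best is None or tcross < best:
            best = float(tcross)
    return best if best is not None and best <= duration_s else None


def load_task_config(path: str | Path) -> tuple[ContrastGrid, RewardMapping]:
    """Read grid/reward parameters from a YAML config.

    Expected keys: ``grid.lower``, ``grid.upper``, ``grid.width``,
    ``reward.height``, ``reward.half_width``; missing keys fall back to the
    task defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    g = cfg.get("grid", {})
    r = cfg.get("reward", {})
    grid = make_grid(g.get("lower", 10.0), g.get("upper", 100.0), g.get("width", 0.61))
    mapping = RewardMapping(height=int(r.get("height", 25)),
                            half_width=float(r.get("half_width", 15.0)))
    return grid, mapping
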
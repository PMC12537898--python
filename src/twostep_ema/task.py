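"""Two-step sequential decision task: environment, payoff walks, trial I/O.

The task has one first-stage state with two actions. Each first-stage action
leads predominantly to one of two second-stage states (the *common*
transition) and with the complementary probability to the other (*rare*).
Each second-stage state offers two actions whose payoffs are nonzero
integer points in ``{payoff_min..-1, +1..payoff_max}`` drifting over trials
according to Gaussian random walks with reflecting boundaries.

Conventions
-----------
* Actions and second-stage states are coded 0/1. The common second-stage
  state of first-stage action ``a`` is state ``a`` (see :func:`common_state`).
* Trials are numbered 1-based in files and 0-based in in-memory arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["subject", "trial", "a1", "transition", "s2", "a2", "points"]

TRANSITION_LABELS = ("common", "rare")


def common_state(a1: int) -> int:
    """Second-stage state reached by the common transition of action ``a1``."""
    return int(a1)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step environment.

    Parameters
    ----------
    n_trials:
        Number of trials in a session (default 201).
    p_common:
        Probability of the common transition, in (0.5, 1].
    walk_sd:
        Standard deviation of the Gaussian increments of the latent payoff
        walks, in points per trial.
    payoff_min, payoff_max:
        Bounds of the payoff range; delivered points are nonzero integers
        in ``{payoff_min..-1, +1..payoff_max}``.
    """

    n_trials: int = 201
    p_common: float = 0.7
    walk_sd: float = 2.0
    payoff_min: int = -5
    payoff_max: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(
                f"p_common must be in (0.5, 1], got {self.p_common}"
            )
        if not math.isfinite(self.walk_sd) or self.walk_sd < 0:
            raise ValueError(f"walk_sd must be finite and >= 0, got {self.walk_sd}")
        if not (self.payoff_min < 0 < self.payoff_max):
            raise ValueError(
                "payoff bounds must straddle zero: "
                f"payoff_min={self.payoff_min}, payoff_max={self.payoff_max}"
            )


@dataclass
class PayoffWalks:
    """Payoff sequences for the four second-stage actions.

    ``values[t, s, a]`` is the integer payoff delivered when action ``a`` is
    taken in second-stage state ``s`` on trial ``t``; ``latent`` holds the
    underlying continuous walk values.
    """

    values: np.ndarray  # (n_trials, 2, 2) int
    latent: np.ndarray  # (n_trials, 2, 2) float
    config: TaskConfig = field(repr=False, default=None)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold ``x`` back into ``[lo, hi]`` by reflection at the boundaries."""
    width = hi - lo
    if width <= 0:
        raise ValueError("empty reflection interval")
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def _round_nonzero(latent: float, lo: int, hi: int, rng: np.random.Generator) -> int:
    """Round a latent walk value to the nearest allowed nonzero integer.

    Values in (-0.5, 0.5) round away from zero toward the latent sign;
    exactly 0 maps to +1 or -1 by a fair coin.
    """
    v = int(round(latent))
    if v == 0:
        if latent > 0:
            v = 1
        elif latent < 0:
            v = -1
        else:
            v = 1 if rng.random() < 0.5 else -1
    return int(min(max(v, lo), hi))


def generate_payoff_walks(
    config: TaskConfig,
    rng: np.random.Generator,
    start: Optional[np.ndarray] = None,
) -> PayoffWalks:
    """Simulate Gaussian payoff random walks with reflecting boundaries.

    Parameters
    ----------
    config:
        Task configuration; ``walk_sd`` sets the increment scale.
    rng:
        Source of randomness.
    start:
        Optional (2, 2) array of initial latent values; by default drawn
        uniformly from the payoff range.
    """
    lo, hi = float(config.payoff_min), float(config.payoff_max)
    if start is None:
        latent0 = rng.uniform(lo, hi, size=(2, 2))
    else:
        latent0 = np.broadcast_to(np.asarray(start, dtype=float), (2, 2)).copy()
        if np.any(latent0 < lo) or np.any(latent0 > hi):
            raise ValueError("start values outside payoff bounds")

    n = config.n_trials
    latent = np.empty((n, 2, 2), dtype=float)
    values = np.empty((n, 2, 2), dtype=np.int64)
    cur = latent0.copy()
    for t in range(n):
        if t > 0:
            steps = rng.normal(0.0, config.walk_sd, size=(2, 2))
            for s in range(2):
                for a in range(2):
                    cur[s, a] = _reflect(cur[s, a] + steps[s, a], lo, hi)
        latent[t] = cur
        for s in range(2):
            for a in range(2):
                values[t, s, a] = _round_nonzero(
                    cur[s, a], config.payoff_min, config.payoff_max, rng
                )
    return PayoffWalks(values=values, latent=latent, config=config)


def sample_transition(
    a1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the second-stage state reached by first-stage action ``a1``.

    Returns ``(s2, label)`` where ``label`` is ``"common"`` or ``"rare"``.
    """
    if a1 not in (0, 1):
        raise ValueError(f"a1 must be 0 or 1, got {a1}")
    if rng.random() < config.p_common:
        return common_state(a1), "common"
    return 1 - common_state(a1), "rare"


def transition_label(a1: int, s2: int) -> str:
    """Label a realized transition as common or rare under the task mapping."""
    return "common" if s2 == common_state(a1) else "rare"


def _fail(row: int, fieldname: str, msg: str) -> None:
    raise ValueError(f"trials row {row}, field '{fieldname}': {msg}")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; raise naming row and field."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    for i, row in enumerate(df.itertuples(index=False)):
        for fieldname in ("a1", "s2", "a2"):
            v = getattr(row, fieldname)
            if v not in (0, 1):
                _fail(i, fieldname, f"must be 0 or 1, got {v!r}")
        if row.points == 0:
            _fail(i, "points", "payoff of 0 is not in the task's payoff set")
        if row.transition not in TRANSITION_LABELS:
            _fail(i, "transition", f"must be one of {TRANSITION_LABELS}")
        expected = transition_label(row.a1, row.s2)
        if row.transition != expected:
            _fail(
                i,
                "transition",
                f"label '{row.transition}' inconsistent with (a1={row.a1}, "
                f"s2={row.s2}); expected '{expected}'",
            )
        if row.trial < 1:
            _fail(i, "trial", "trial index is 1-based")
    return df


def write_trials(records: pd.DataFrame | Iterable[dict], path) -> None:
    """Write a trial table to CSV after schema validation."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df = validate_trials(df)
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    df = pd.read_csv(path)
    return validate_trials(df)
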
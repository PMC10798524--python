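"""Structured gain-only choice sets for the risky-decision task.

The task presents a sequence of binary choices between a safe amount
(paid with certainty) and a gamble paying either $0 or roughly double
the safe amount, each with probability one half.  Trials are organised
into *runs* sharing a common expected-value (EV) level; consecutive runs
are separated by signed EV *shifts* drawn from a fixed dollar grid.
Option amounts within a run are the EV level plus independent uniform
noise, so consecutive trials are highly correlated in value — the
temporal structure that creates context at the "neighborhood" timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RunPlan",
    "TaskConfig",
    "make_run_structure",
    "assign_ev_levels",
    "realize_trials",
    "generate_choice_set",
    "option_evs",
    "CHOICE_SET_COLUMNS",
]

#: default shift-magnitude grid: $5 to $15 in $1.25 increments (in cents)
DEFAULT_SHIFT_GRID = tuple(500 + 125 * k for k in range(9))

#: EV levels live on a quarter-dollar grid so $1.25 shifts stay on-grid
LEVEL_GRID_CENTS = 25

CHOICE_SET_COLUMNS = [
    "trial_index",
    "run_id",
    "ev_level",
    "safe",
    "risky_gain",
    "risky_loss",
    "p_win",
    "shift",
    "iti",
]


class TaskConfigError(ValueError):
    """A task configuration that cannot produce a valid choice set."""


@dataclass(frozen=True)
class RunPlan:
    """Run lengths plus (optionally) the EV level of each run.

    All dollar quantities are stored in cents to keep the level/shift
    grids exact; accessors return dollars.
    """

    run_lengths: tuple[int, ...]
    ev_levels_cents: tuple[int, ...] = ()
    shifts_cents: tuple[int, ...] = ()

    @property
    def n_trials(self) -> int:
        return int(sum(self.run_lengths))

    @property
    def n_runs(self) -> int:
        return len(self.run_lengths)

    @property
    def ev_levels(self) -> np.ndarray:
        return np.asarray(self.ev_levels_cents, dtype=float) / 100.0

    @property
    def shifts(self) -> np.ndarray:
        return np.asarray(self.shifts_cents, dtype=float) / 100.0


@dataclass(frozen=True)
class TaskConfig:
    """Default task parameters (240 trials, 9-10 runs of 9-36 trials)."""

    n_trials: int = 240
    n_runs_range: tuple[int, int] = (9, 10)
    length_range: tuple[int, int] = (9, 36)
    shift_grid_cents: tuple[int, ...] = DEFAULT_SHIFT_GRID
    level_bounds_cents: tuple[int, int] = (225, 3300)
    noise_half_width: float = 2.0
    safe_bounds: tuple[float, float] = (0.25, 35.0)
    risky_bounds: tuple[float, float] = (0.50, 70.0)
    iti_range: tuple[float, float] = (1.5, 4.5)


def make_run_structure(
    n_trials: int = 240,
    n_runs_range: tuple[int, int] = (9, 10),
    length_range: tuple[int, int] = (9, 36),
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 200_000,
) -> RunPlan:
    """Sample run lengths: a uniform composition of ``n_trials``.

    The number of runs is drawn uniformly from the feasible values in
    ``n_runs_range``; lengths are then drawn i.i.d. uniform on
    ``length_range`` and accepted only when they sum to ``n_trials``,
    which yields a uniform draw from the bounded integer compositions.
    """
    rng = np.random.default_rng(seed)
    k_lo, k_hi = int(n_runs_range[0]), int(n_runs_range[1])
    l_lo, l_hi = int(length_range[0]), int(length_range[1])
    if not (1 <= k_lo <= k_hi and 1 <= l_lo <= l_hi):
        raise TaskConfigError(
            f"invalid ranges: runs {n_runs_range}, lengths {length_range}"
        )
    feasible = [k for k in range(k_lo, k_hi + 1) if k * l_lo <= n_trials <= k * l_hi]
    if not feasible:
        raise TaskConfigError(
            f"n_trials={n_trials} is outside the achievable range "
            f"[{k_lo * l_lo}, {k_hi * l_hi}] for {k_lo}-{k_hi} runs of "
            f"{l_lo}-{l_hi} trials"
        )
    k = int(rng.choice(feasible))
    if k * l_lo == n_trials:
        return RunPlan(run_lengths=(l_lo,) * k)
    for _ in range(max_attempts):
        lengths = rng.integers(l_lo, l_hi + 1, size=k)
        if lengths.sum() == n_trials:
            return RunPlan(run_lengths=tuple(int(x) for x in lengths))
    raise TaskConfigError(
        f"rejection sampling failed to hit n_trials={n_trials} in "
        f"{max_attempts} attempts (runs={k}, lengths in [{l_lo},{l_hi}])"
    )


def assign_ev_levels(
    plan: RunPlan,
    shift_grid_cents: tuple[int, ...] = DEFAULT_SHIFT_GRID,
    level_bounds_cents: tuple[int, int] = (225, 3300),
    seed: int | np.random.Generator | None = None,
) -> RunPlan:
    """Attach an EV level to each run by a random walk on the shift grid.

    The initial level is uniform on the admissible quarter-dollar grid;
    each subsequent level adds a signed shift drawn uniformly from the
    grid elements that keep the level inside ``level_bounds_cents``.
    """
    rng = np.random.default_rng(seed)
    if not shift_grid_cents:
        raise TaskConfigError("shift grid is empty")
    lo, hi = level_bounds_cents
    if hi - lo < max(shift_grid_cents):
        raise TaskConfigError(
            f"level bounds {level_bounds_cents} narrower than the largest "
            f"shift {max(shift_grid_cents)}: dead ends would be unavoidable"
        )
    grid = np.arange(
        -(-lo // LEVEL_GRID_CENTS) * LEVEL_GRID_CENTS, hi + 1, LEVEL_GRID_CENTS
    )
    level = int(rng.choice(grid))
    levels = [level]
    shifts: list[int] = []
    for _ in range(plan.n_runs - 1):
        candidates = [
            s * sign
            for s in shift_grid_cents
            for sign in (+1, -1)
            if lo <= level + s * sign <= hi
        ]
        if not candidates:  # unreachable under the precondition above
            raise TaskConfigError(f"no admissible shift from level {level} cents")
        step = int(rng.choice(candidates))
        shifts.append(step)
        level += step
        levels.append(level)
    return replace(
        plan, ev_levels_cents=tuple(levels), shifts_cents=tuple(shifts)
    )


def realize_trials(
    plan: RunPlan,
    noise_half_width: float = 2.0,
    seed: int | np.random.Generator | None = None,
    config: TaskConfig | None = None,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Realize per-trial option amounts from a fully specified plan.

    ``safe = round(L + u1, 2)`` and ``risky_gain = round(2 * (L + u2), 2)``
    with u1, u2 independent uniform on ±``noise_half_width``; amounts
    falling outside the configured bounds are redrawn.  Also draws the
    inter-trial interval used later for SCR event timing.
    """
    if noise_half_width < 0:
        raise TaskConfigError("noise_half_width must be >= 0")
    if not plan.ev_levels_cents:
        raise TaskConfigError("plan has no EV levels; call assign_ev_levels first")
    cfg = config or TaskConfig(noise_half_width=noise_half_width)
    rng = np.random.default_rng(seed)

    rows = []
    t = 0
    for run_id, (length, level_c) in enumerate(
        zip(plan.run_lengths, plan.ev_levels_cents), start=1
    ):
        level = level_c / 100.0
        shift = plan.shifts_cents[run_id - 2] / 100.0 if run_id > 1 else 0.0
        for j in range(length):
            for _ in range(max_redraws):
                safe = round(level + rng.uniform(-noise_half_width, noise_half_width), 2)
                if cfg.safe_bounds[0] <= safe <= cfg.safe_bounds[1]:
                    break
            else:
                raise TaskConfigError(
                    f"safe amount around level ${level:.2f} kept violating "
                    f"bounds {cfg.safe_bounds}; widen level bounds"
                )
            for _ in range(max_redraws):
                risky = round(
                    2.0 * (level + rng.uniform(-noise_half_width, noise_half_width)), 2
                )
                if cfg.risky_bounds[0] <= risky <= cfg.risky_bounds[1]:
                    break
            else:
                raise TaskConfigError(
                    f"risky amount around level ${level:.2f} kept violating "
                    f"bounds {cfg.risky_bounds}; widen level bounds"
                )
            t += 1
            rows.append(
                {
                    "trial_index": t,
                    "run_id": run_id,
                    "ev_level": level,
                    "safe": safe,
                    "risky_gain": risky,
                    "risky_loss": 0.0,
                    "p_win": 0.5,
                    "shift": shift if j == 0 else 0.0,
                    "iti": rng.uniform(*cfg.iti_range),
                }
            )
    return pd.DataFrame(rows, columns=CHOICE_SET_COLUMNS)


def generate_choice_set(
    config: TaskConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full choice-set generation: structure, levels, realized amounts."""
    cfg = config or TaskConfig()
    rng = np.random.default_rng(seed)
    plan = make_run_structure(
        cfg.n_trials, cfg.n_runs_range, cfg.length_range, seed=rng
    )
    plan = assign_ev_levels(
        plan, cfg.shift_grid_cents, cfg.level_bounds_cents, seed=rng
    )
    return realize_trials(plan, cfg.noise_half_width, seed=rng, config=cfg)


def option_evs(
    risky_gain: float, safe: float, p_win: float = 0.5, risky_loss: float = 0.0
) -> tuple[float, float]:
    """Expected values of (risky, safe): probability-weighted outcomes.

    E.g. a gamble paying +$30 or $0 with p = .5 against a safe $16 has
    EVs ($15, $16).
    """
    return (p_win * risky_gain + (1.0 - p_win) * risky_loss, 1.0 * safe)
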
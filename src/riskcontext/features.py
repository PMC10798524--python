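"""Normalized per-trial regressors for the choice and SCR models.

All dollar-valued regressors (option amounts, previous outcome, shifts)
are divided by a single ``money_scale``; the two slowly growing
regressors (cumulative earnings and the linear expectation) are divided
by ``earnings_scale`` so that every regressor is O(1) and the printed
coefficient magnitudes are comparable across terms.

The scales are not identifiable from the models themselves, so they are
explicit and overridable.  The defaults — the dataset's maximum possible
outcome for ``money_scale`` and the expected total earnings for
``earnings_scale`` — reproduce the published probability translations
(a −0.15 coefficient on previous outcome mapping to a 3.7-point drop in
gamble probability after a maximal $68 outcome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationScheme",
    "linear_expectation",
    "build_features",
    "build_cohort_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "subject",
    "trial_index",
    "choice",
    "choice_sym",
    "riskygain",
    "safe",
    "magnitude",
    "outcome",
    "prev_outcome",
    "pos_shift",
    "neg_shift",
    "pos_shift_prev",
    "earnings",
    "expectation",
]


@dataclass(frozen=True)
class NormalizationScheme:
    """Fixed dollar divisors applied before any model is fitted."""

    money_scale: float
    earnings_scale: float

    def __post_init__(self) -> None:
        if self.money_scale <= 0 or self.earnings_scale <= 0:
            raise ValueError("normalization scales must be positive")

    @classmethod
    def from_choice_sets(cls, choice_sets: Iterable[pd.DataFrame]) -> "NormalizationScheme":
        """money_scale = maximum possible outcome; earnings_scale =
        expected total earnings (sum of per-trial EV levels), averaged
        over subjects when schedules differ."""
        sets = list(choice_sets)
        if not sets:
            raise ValueError("need at least one choice set")
        money = max(float(cs["risky_gain"].max()) for cs in sets)
        earn = float(np.mean([cs["ev_level"].sum() for cs in sets]))
        return cls(money_scale=money, earnings_scale=earn)

    @classmethod
    def from_choice_set(cls, choice_set: pd.DataFrame) -> "NormalizationScheme":
        return cls.from_choice_sets([choice_set])


def linear_expectation(choice_set: pd.DataFrame) -> np.ndarray:
    """Straight-line earnings forecast: t times the task-mean EV level.

    The slope depends only on the task-level mean, so the expectation at
    the final trial equals the expected total earnings.
    """
    mean_ev = float(choice_set["ev_level"].mean())
    t = choice_set["trial_index"].to_numpy(dtype=float)
    return t * mean_ev


def build_features(
    choice_set: pd.DataFrame,
    records: pd.DataFrame,
    norm: NormalizationScheme,
    subject: int | str = 0,
) -> pd.DataFrame:
    """One row per retained trial with normalized regressors.

    Cumulative earnings at trial t sum the outcomes of trials 1..t-1
    (the pre-decision information set).  Trial 1, missed trials, and
    trials whose predecessor was missed (previous outcome undefined) are
    excluded, mirroring listwise deletion.
    """
    cs = choice_set.reset_index(drop=True)
    rec = records.reset_index(drop=True)
    if len(cs) != len(rec):
        raise ValueError(
            f"choice set has {len(cs)} trials but records have {len(rec)}"
        )
    if not np.array_equal(
        cs["trial_index"].to_numpy(), rec["trial_index"].to_numpy()
    ):
        raise ValueError("choice set and records are misaligned on trial_index")
    missed = rec["missed"].to_numpy(dtype=bool)
    outcome = rec["outcome"].to_numpy(dtype=float)
    if np.isnan(outcome[~missed]).any():
        raise ValueError("non-missed trials with missing outcomes")

    m = norm.money_scale
    shift = cs["shift"].to_numpy(dtype=float)
    pos_shift = np.clip(shift, 0.0, None) / m
    neg_shift = np.clip(shift, None, 0.0) / m
    outcome_filled = np.where(missed, 0.0, outcome)
    earnings_before = np.concatenate([[0.0], np.cumsum(outcome_filled)[:-1]])

    df = pd.DataFrame(
        {
            "subject": subject,
            "trial_index": cs["trial_index"].to_numpy(),
            "choice": rec["choice"].to_numpy(dtype=float),
            "riskygain": cs["risky_gain"].to_numpy(dtype=float) / m,
            "safe": cs["safe"].to_numpy(dtype=float) / m,
            "magnitude": cs["ev_level"].to_numpy(dtype=float) / m,
            "outcome": outcome / m,
            "prev_outcome": np.concatenate([[np.nan], outcome[:-1]]) / m,
            "pos_shift": pos_shift,
            "neg_shift": neg_shift,
            "pos_shift_prev": np.concatenate([[0.0], pos_shift[:-1]]),
            "earnings": earnings_before / norm.earnings_scale,
            "expectation": linear_expectation(cs) / norm.earnings_scale,
        }
    )
    df["choice_sym"] = 2.0 * df["choice"] - 1.0

    prev_missed = np.concatenate([[True], missed[:-1]])  # trial 1 has no predecessor
    keep = ~missed & ~prev_missed
    out = df.loc[keep, FEATURE_COLUMNS].reset_index(drop=True)
    return out


def build_cohort_features(
    choice_sets: dict | list,
    records: dict | list,
    norm: NormalizationScheme | None = None,
) -> pd.DataFrame:
    """Stack per-subject feature tables under a shared normalization."""
    if isinstance(choice_sets, dict):
        keys = sorted(choice_sets)
        sets = [choice_sets[k] for k in keys]
        recs = [records[k] for k in keys]
    else:
        keys = list(range(len(choice_sets)))
        sets, recs = list(choice_sets), list(records)
    if norm is None:
        norm = NormalizationScheme.from_choice_sets(sets)
    parts = [
        build_features(cs, rec, norm, subject=k)
        for k, cs, rec in zip(keys, sets, recs)
    ]
    return pd.concat(parts, ignore_index=True)
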
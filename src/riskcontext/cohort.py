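"""Synthetic subjects: context-sensitive choices and 200 Hz SCR traces.

Choices are generated from the hierarchical logistic model the analysis
fits: a linear predictor combining current-trial amounts (risky gain,
safe, EV-level magnitude, with correlated subject-level slope deviations
on the first two plus a subject intercept) and temporal-context terms
(previous outcome, signed EV shifts, cumulative earnings, a linear
expectation, and the earnings-by-previous-outcome interaction), all on
the normalized regressor scale used for estimation.  Gamble outcomes are
fair coin flips paying the risky gain or $0.

Skin-conductance traces are built by superposing a canonical response
kernel (difference of exponentials, unit peak) at event onsets on a slow
baseline drift plus white noise.  Outcome-locked amplitudes increase
with cumulative earnings; decision-locked amplitudes increase with
positive EV shifts — the two generative effects the SCR model suite is
asked to recover.  Generative amplitude coefficients are stated on the
sqrt/max-normalized scale and converted to µS via a configurable
subject-level maximum amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import NormalizationScheme, linear_expectation
from .task import TaskConfig, generate_choice_set

__all__ = [
    "ScrGenParams",
    "SubjectParams",
    "PopulationConfig",
    "SCRKernel",
    "SCRTrace",
    "sample_subject_params",
    "simulate_choices",
    "event_schedule",
    "synthesize_scr_trace",
    "simulate_cohort",
]

RECORD_COLUMNS = ["trial_index", "choice", "outcome", "rt", "missed"]


@dataclass(frozen=True)
class ScrGenParams:
    """Generative SCR amplitude model (normalized sqrt/max scale)."""

    level_outcome: float = 0.65       # baseline outcome-locked amplitude
    gain_earnings: float = 0.12       # per unit normalized cumulative earnings
    level_decision: float = 0.50      # baseline decision-locked amplitude
    gain_pos_shift: float = 0.41      # per unit normalized positive shift
    max_amplitude_us: float = 0.40    # subject maximum SCR, µS
    nonresponse_prob_outcome: float = 0.45
    nonresponse_prob_decision: float = 0.50
    amp_noise_sd: float = 0.10        # amplitude noise, normalized scale
    trace_noise_sd: float = 0.003     # white measurement noise, µS

    def __post_init__(self) -> None:
        for p in (self.nonresponse_prob_outcome, self.nonresponse_prob_decision):
            if not 0.0 <= p <= 1.0:
                raise ValueError("nonresponse probabilities must be in [0, 1]")
        if self.amp_noise_sd < 0 or self.trace_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject coefficients on the normalized regressor scale.

    Defaults are the published fixed-effect estimates from the
    current-trial model and the full context model (previous outcome
    −0.7, positive shift 5.3, earnings 0.37, expectation −0.26,
    earnings-by-previous-outcome interaction 1.3).
    """

    b_riskygain: float = 30.88
    b_safe: float = -13.18
    b_magnitude: float = -49.51
    b_prev_outcome: float = -0.7
    b_pos_shift: float = 5.3
    b_neg_shift: float = 0.0
    b_earnings: float = 0.37
    b_expectation: float = -0.26
    b_interaction: float = 1.3
    re_intercept: float = 0.0
    re_riskygain: float = 0.0
    re_safe: float = 0.0
    scr: ScrGenParams = field(default_factory=ScrGenParams)
    rt_range: tuple[float, float] = (0.3, 2.0)


CONTEXT_TERMS = (
    "b_prev_outcome",
    "b_pos_shift",
    "b_neg_shift",
    "b_earnings",
    "b_expectation",
    "b_interaction",
)


@dataclass(frozen=True)
class PopulationConfig:
    """Population distribution from which subjects are drawn.

    Coefficients are normal around ``mean`` with per-coefficient SDs
    (default 0: every subject shares the published fixed effects, and
    between-subject variation enters only through the random intercept
    and the correlated risky-gain/safe slope deviations — the structure
    the fitted models actually represent).
    """

    mean: SubjectParams = field(default_factory=SubjectParams)
    coef_sds: dict[str, float] = field(default_factory=dict)
    re_sd_riskygain: float = 2.5
    re_sd_safe: float = 2.5
    re_corr: float = -0.3
    re_sd_intercept: float = 0.3

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.coef_sds.values()):
            raise ValueError("coefficient SDs must be >= 0")
        if min(self.re_sd_riskygain, self.re_sd_safe, self.re_sd_intercept) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not -1.0 < self.re_corr < 1.0:
            raise ValueError("re_corr must be in (-1, 1)")

    def null_context(self) -> "PopulationConfig":
        """Copy with every context coefficient set to zero."""
        mean = replace(self.mean, **{k: 0.0 for k in CONTEXT_TERMS})
        return replace(self, mean=mean)


def sample_subject_params(
    population: PopulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> SubjectParams:
    """Draw one subject from the population distribution."""
    pop = population or PopulationConfig()
    rng = np.random.default_rng(seed)
    updates: dict[str, float] = {}
    for name, sd in pop.coef_sds.items():
        if not hasattr(pop.mean, name):
            raise ValueError(f"unknown coefficient {name!r} in coef_sds")
        updates[name] = getattr(pop.mean, name) + sd * rng.standard_normal()
    z1, z2 = rng.standard_normal(2)
    rho = pop.re_corr
    updates["re_riskygain"] = float(pop.re_sd_riskygain * z1)
    updates["re_safe"] = float(
        pop.re_sd_safe * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    )
    updates["re_intercept"] = float(pop.re_sd_intercept * rng.standard_normal())
    return replace(pop.mean, **updates)


def simulate_choices(
    choice_set: pd.DataFrame,
    params: SubjectParams,
    norm: NormalizationScheme,
    seed: int | np.random.Generator | None = None,
    miss_rate: float = 0.005,
) -> pd.DataFrame:
    """Sequentially simulate choices and outcomes for one subject.

    Context regressors are computed from the realized history as trials
    unfold (earnings accumulate forward); the normalization is fixed
    before simulation.  Missed trials are injected uniformly at random
    and carry no choice or outcome.
    """
    rng = np.random.default_rng(seed)
    n = len(choice_set)
    m = norm.money_scale
    rg = choice_set["risky_gain"].to_numpy(dtype=float)
    rg_n = rg / m
    safe = choice_set["safe"].to_numpy(dtype=float)
    safe_n = safe / m
    mag_n = choice_set["ev_level"].to_numpy(dtype=float) / m
    shift = choice_set["shift"].to_numpy(dtype=float)
    pos_n = np.clip(shift, 0.0, None) / m
    neg_n = np.clip(shift, None, 0.0) / m
    exp_n = linear_expectation(choice_set) / norm.earnings_scale

    base = (
        (params.b_riskygain + params.re_riskygain) * rg_n
        + (params.b_safe + params.re_safe) * safe_n
        + params.b_magnitude * mag_n
        + params.re_intercept
    )
    u_choice = rng.random(n)
    u_win = rng.random(n)
    u_miss = rng.random(n)
    rts = rng.uniform(*params.rt_range, size=n)

    choice = np.full(n, np.nan)
    outcome = np.full(n, np.nan)
    missed = u_miss < miss_rate
    earnings = 0.0  # dollars accumulated before the current trial
    prev_out_n = 0.0  # normalized outcome of the previous (non-missed) trial
    prev_valid = False
    for t in range(n):
        if missed[t]:
            prev_valid = False
            continue
        earn_n = earnings / norm.earnings_scale
        eta = base[t] + params.b_pos_shift * pos_n[t] + params.b_neg_shift * neg_n[t]
        eta += params.b_earnings * earn_n + params.b_expectation * exp_n[t]
        if prev_valid:
            eta += params.b_prev_outcome * prev_out_n
            eta += params.b_interaction * earn_n * prev_out_n
        p = 1.0 / (1.0 + np.exp(-eta))
        c = 1.0 if u_choice[t] < p else 0.0
        if c == 1.0:
            out = rg[t] if u_win[t] < 0.5 else 0.0
        else:
            out = safe[t]
        choice[t] = c
        outcome[t] = out
        earnings += out
        prev_out_n = out / m
        prev_valid = True

    rts[missed] = np.nan
    return pd.DataFrame(
        {
            "trial_index": choice_set["trial_index"].to_numpy(),
            "choice": choice,
            "outcome": outcome,
            "rt": rts,
            "missed": missed,
        },
        columns=RECORD_COLUMNS,
    )


@dataclass(frozen=True)
class SCRKernel:
    """Canonical skin-conductance response: difference of exponentials
    scaled to unit peak, with a fixed onset latency."""

    tau_rise: float = 0.75
    tau_decay: float = 2.0
    latency: float = 1.0
    duration: float = 12.0

    def sample(self, fs: float) -> np.ndarray:
        n_lat = int(round(self.latency * fs))
        t = np.arange(int(round(self.duration * fs))) / fs
        h = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        peak = h.max()
        if peak <= 0:
            raise ValueError("kernel has no positive peak; check time constants")
        return np.concatenate([np.zeros(n_lat), h / peak])


@dataclass
class SCRTrace:
    """A sampled conductance series plus event markers."""

    fs: float
    values: np.ndarray
    events: pd.DataFrame  # columns: onset, kind, trial_index

    def __post_init__(self) -> None:
        onsets = self.events["onset"].to_numpy(dtype=float)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs


def event_schedule(
    records: pd.DataFrame, choice_set: pd.DataFrame, lead_in: float = 5.0
) -> pd.DataFrame:
    """Per-trial event times from the task's fixed timing structure.

    Options are shown for a 2 s forced-viewing period followed by a 2 s
    response window; a 0.5 s ISI precedes a 1 s outcome display; the
    unused part of the response window is added to the variable ITI.
    Missed trials consume the full response window and show no outcome.
    """
    iti = choice_set["iti"].to_numpy(dtype=float)
    rt = records["rt"].to_numpy(dtype=float)
    missed = records["missed"].to_numpy(dtype=bool)
    rows = []
    t0 = lead_in
    for i, trial in enumerate(choice_set["trial_index"].to_numpy()):
        if missed[i]:
            rows.append(
                {"trial_index": trial, "decision_onset": t0,
                 "response_time": np.nan, "outcome_onset": np.nan}
            )
            t0 = t0 + 2.0 + 2.0 + 0.5 + 1.0 + iti[i]
            continue
        response = t0 + 2.0 + rt[i]
        outcome_onset = response + 0.5
        rows.append(
            {"trial_index": trial, "decision_onset": t0,
             "response_time": response, "outcome_onset": outcome_onset}
        )
        t0 = outcome_onset + 1.0 + iti[i] + (2.0 - rt[i])
    return pd.DataFrame(rows)


def _normalized_to_us(n_amp: float, max_us: float) -> float:
    """Invert sqrt/max normalization: a = n^2 * a_max, clipped at 0."""
    return max(0.0, n_amp) ** 2 * max_us


def synthesize_scr_trace(
    records: pd.DataFrame,
    choice_set: pd.DataFrame,
    params: SubjectParams,
    norm: NormalizationScheme,
    seed: int | np.random.Generator | None = None,
    kernel: SCRKernel | None = None,
    fs: float = 200.0,
    lead_in: float = 5.0,
    tail: float = 10.0,
    baseline: float = 2.0,
    drift_amp: float = 0.02,
    drift_period: float = 120.0,
) -> SCRTrace:
    """Superpose event-locked responses on a drifting baseline.

    Overlapping responses sum; each event is independently zeroed with
    the configured non-response probability.
    """
    rng = np.random.default_rng(seed)
    ker = (kernel or SCRKernel()).sample(fs)
    sched = event_schedule(records, choice_set, lead_in=lead_in)
    missed = records["missed"].to_numpy(dtype=bool)
    outcome = records["outcome"].to_numpy(dtype=float)
    shift = choice_set["shift"].to_numpy(dtype=float)
    pos_n = np.clip(shift, 0.0, None) / norm.money_scale
    earnings_before = np.concatenate(
        [[0.0], np.cumsum(np.where(missed, 0.0, outcome))[:-1]]
    ) / norm.earnings_scale

    g = params.scr
    end = float(np.nanmax(sched[["decision_onset", "outcome_onset"]].to_numpy())) + tail
    n_samples = int(round(end * fs))
    t = np.arange(n_samples) / fs
    values = baseline + drift_amp * np.sin(2 * np.pi * t / drift_period)
    if g.trace_noise_sd > 0:
        values = values + rng.normal(0.0, g.trace_noise_sd, size=n_samples)

    ev_rows = []
    for i in range(len(sched)):
        trial = int(sched.at[i, "trial_index"])
        t_dec = sched.at[i, "decision_onset"]
        amp_n = g.level_decision + g.gain_pos_shift * pos_n[i]
        amp_n += g.amp_noise_sd * rng.standard_normal()
        if rng.random() < g.nonresponse_prob_decision:
            amp_n = 0.0
        _add_event(values, ker, fs, t_dec, _normalized_to_us(amp_n, g.max_amplitude_us))
        ev_rows.append({"onset": t_dec, "kind": "decision", "trial_index": trial})
        if missed[i]:
            continue
        ev_rows.append(
            {"onset": sched.at[i, "response_time"], "kind": "response",
             "trial_index": trial}
        )
        t_out = sched.at[i, "outcome_onset"]
        amp_n = g.level_outcome + g.gain_earnings * earnings_before[i]
        amp_n += g.amp_noise_sd * rng.standard_normal()
        if rng.random() < g.nonresponse_prob_outcome:
            amp_n = 0.0
        _add_event(values, ker, fs, t_out, _normalized_to_us(amp_n, g.max_amplitude_us))
        ev_rows.append({"onset": t_out, "kind": "outcome", "trial_index": trial})

    events = pd.DataFrame(ev_rows).sort_values("onset", kind="stable").reset_index(drop=True)
    return SCRTrace(fs=fs, values=values, events=events)


def _add_event(values: np.ndarray, ker: np.ndarray, fs: float, onset: float, amp: float) -> None:
    if amp <= 0:
        return
    i0 = int(round(onset * fs))
    i1 = min(i0 + len(ker), len(values))
    if i0 >= len(values):
        return
    values[i0:i1] += amp * ker[: i1 - i0]


def simulate_cohort(
    n_subjects: int = 60,
    task: TaskConfig | None = None,
    population: PopulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
    miss_rate: float = 0.005,
    norm: NormalizationScheme | None = None,
    shared_design: pd.DataFrame | None = None,
):
    """Generate a full behavioral cohort.

    Returns ``(choice_sets, records, params, norm)`` where the first two
    are dicts keyed by subject id.  Each subject gets an independently
    sampled task schedule unless ``shared_design`` is supplied.
    """
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else None)
    if not isinstance(seed, int):
        rng_master = np.random.default_rng(seed)
        ss = np.random.SeedSequence(int(rng_master.integers(2**31)))
    children = ss.spawn(2 * n_subjects)
    pop = population or PopulationConfig()
    cfg = task or TaskConfig()

    choice_sets = {
        s: (shared_design if shared_design is not None
            else generate_choice_set(cfg, seed=np.random.default_rng(children[2 * s])))
        for s in range(n_subjects)
    }
    if norm is None:
        norm = NormalizationScheme.from_choice_sets(choice_sets.values())
    records = {}
    params = {}
    for s in range(n_subjects):
        rng = np.random.default_rng(children[2 * s + 1])
        params[s] = sample_subject_params(pop, seed=rng)
        records[s] = simulate_choices(
            choice_sets[s], params[s], norm, seed=rng, miss_rate=miss_rate
        )
    return choice_sets, records, params, norm
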
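"""Skin-conductance preprocessing and event scoring.

The published recipe: a 16-tap FIR low-pass at 25 Hz, mean-value
smoothing with a three-sample Blackman window, trough-to-peak amplitude
in a 0.5-4.5 s window after each event onset with a 0.02 µS floor,
square-root transform and division by the subject's maximum response,
and exclusion of subjects who respond on no more than 25% of events.

Trough-to-peak is the maximum rise above the running minimum inside the
window (not max minus min), so a decline after an early peak cannot
inflate the score — standard electrodermal practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import SCRTrace

__all__ = [
    "ScoredSCR",
    "lowpass_fir",
    "smooth_blackman",
    "preprocess",
    "score_event",
    "score_events",
    "normalize_subject",
    "classify_responder",
    "score_subject",
]

DEFAULT_WINDOW = (0.5, 4.5)
DEFAULT_FLOOR = 0.02
DEFAULT_RESPONDER_FRACTION = 0.25


class TruncatedTrialError(ValueError):
    """A scoring window extends past the end of the recorded trace."""


@dataclass(frozen=True)
class ScoredSCR:
    """Per-event raw and sqrt/max-normalized amplitudes for one subject."""

    raw: np.ndarray          # µS, 0 where below floor
    normalized: np.ndarray   # sqrt(raw) / max(sqrt(raw)), in [0, 1]
    max_sqrt_amplitude: float
    response_fraction: float
    responder: bool


def lowpass_fir(
    trace: SCRTrace, cutoff_hz: float = 25.0, n_coefficients: int = 16
) -> SCRTrace:
    """Windowed-sinc FIR low-pass with group-delay compensation.

    The filter is linear phase with delay (n-1)/2 samples; the output is
    shifted back by the rounded delay so event times stay aligned (for
    the default even tap count the residual is half a sample, 2.5 ms at
    200 samples/s).  Taps are normalized to unit DC gain.
    """
    x = np.asarray(trace.values, dtype=float)
    if len(x) <= n_coefficients:
        raise ValueError(
            f"trace of {len(x)} samples is shorter than the {n_coefficients}-tap filter"
        )
    if trace.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff frequency")
    taps = signal.firwin(n_coefficients, cutoff_hz, fs=trace.fs)
    delay = int(round((n_coefficients - 1) / 2))
    xpad = np.concatenate([x, np.full(delay, x[-1])])
    y = signal.lfilter(taps, 1.0, xpad)[delay:]
    return replace(trace, values=y)


def smooth_blackman(trace: SCRTrace, window_samples: int = 3) -> SCRTrace:
    """Mean-value smoothing with Blackman weights normalized to sum 1.

    The literal N-point Blackman taper is zero at its endpoints, so the
    weights are the interior N points of an (N+2)-point window (for N=3:
    [0.34, 1.0, 0.34] before normalization).  Edges renormalize over the
    partial window.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window_samples must be a positive odd integer")
    if window_samples == 1:
        return replace(trace, values=np.asarray(trace.values, dtype=float).copy())
    w = np.blackman(window_samples + 2)[1:-1]
    x = np.asarray(trace.values, dtype=float)
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return replace(trace, values=num / den)


def preprocess(
    trace: SCRTrace,
    cutoff_hz: float = 25.0,
    n_coefficients: int = 16,
    window_samples: int = 3,
) -> SCRTrace:
    """Low-pass filter then smooth, per the published preprocessing."""
    return smooth_blackman(
        lowpass_fir(trace, cutoff_hz, n_coefficients), window_samples
    )


def score_event(
    trace: SCRTrace,
    onset: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Trough-to-peak amplitude (µS) in a window after ``onset``.

    Amplitude is the largest rise from the running minimum within the
    window; values below ``floor`` score 0.
    """
    i0 = int(round((onset + window[0]) * trace.fs))
    i1 = int(round((onset + window[1]) * trace.fs)) + 1
    if i0 < 0 or i1 > len(trace.values):
        raise TruncatedTrialError(
            f"scoring window [{onset + window[0]:.2f}, {onset + window[1]:.2f}] s "
            f"extends outside the recorded trace (0 to {trace.duration:.2f} s)"
        )
    seg = np.asarray(trace.values[i0:i1], dtype=float)
    rise = float(np.max(seg - np.minimum.accumulate(seg)))
    return rise if rise >= floor else 0.0


def score_events(
    trace: SCRTrace,
    phase: str = "outcome",
    window: tuple[float, float] | None = None,
    floor: float = DEFAULT_FLOOR,
    decision_latency: float = 0.5,
) -> pd.DataFrame:
    """Score every event of one phase; returns trial_index and raw µS.

    For the outcome phase the window is the fixed 0.5-4.5 s interval.
    The decision phase runs from options onset to the response, so its
    window is [onset + 0.5 s, response + 0.5 s], mirroring the half
    second response latency of the outcome window.
    """
    ev = trace.events
    if phase == "outcome":
        sel = ev[ev["kind"] == "outcome"]
        win = window or DEFAULT_WINDOW
        rows = []
        for r in sel.itertuples():
            try:
                amp = score_event(trace, float(r.onset), win, floor)
            except TruncatedTrialError as exc:
                raise TruncatedTrialError(
                    f"trial {int(r.trial_index)}: {exc}"
                ) from None
            rows.append({"trial_index": int(r.trial_index), "raw": amp})
    elif phase == "decision":
        dec = ev[ev["kind"] == "decision"].set_index("trial_index")
        resp = ev[ev["kind"] == "response"].set_index("trial_index")
        rows = []
        for trial, r in dec.iterrows():
            if trial not in resp.index:  # missed trial: no response event
                continue
            onset = float(r["onset"])
            end = float(resp.at[trial, "onset"]) + decision_latency - onset
            rows.append(
                {"trial_index": int(trial),
                 "raw": score_event(trace, onset, (decision_latency, end), floor)}
            )
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return pd.DataFrame(rows, columns=["trial_index", "raw"])


def normalize_subject(amplitudes: np.ndarray) -> ScoredSCR:
    """Square-root each amplitude and divide by the subject maximum.

    An all-zero subject yields all-zero normalized values; otherwise the
    largest response maps to exactly 1.
    """
    raw = np.asarray(amplitudes, dtype=float)
    if (raw < 0).any():
        raise ValueError("amplitudes must be >= 0")
    sqrt_amp = np.sqrt(raw)
    max_sqrt = float(sqrt_amp.max()) if len(raw) else 0.0
    normalized = sqrt_amp / max_sqrt if max_sqrt > 0 else np.zeros_like(raw)
    fraction = float(np.mean(raw > 0)) if len(raw) else 0.0
    return ScoredSCR(
        raw=raw,
        normalized=normalized,
        max_sqrt_amplitude=max_sqrt,
        response_fraction=fraction,
        responder=classify_responder_fraction(fraction),
    )


def classify_responder_fraction(
    fraction: float, min_fraction: float = DEFAULT_RESPONDER_FRACTION
) -> bool:
    return fraction > min_fraction


def classify_responder(
    scored: ScoredSCR, min_fraction: float = DEFAULT_RESPONDER_FRACTION
) -> bool:
    """Responder iff strictly more than ``min_fraction`` of events have a
    nonzero scored response."""
    if len(scored.raw) == 0:
        raise ValueError("no scored events")
    return scored.response_fraction > min_fraction


def score_subject(
    trace: SCRTrace,
    phase: str = "outcome",
    cutoff_hz: float = 25.0,
    n_coefficients: int = 16,
    window_samples: int = 3,
    window: tuple[float, float] | None = None,
    floor: float = DEFAULT_FLOOR,
    min_fraction: float = DEFAULT_RESPONDER_FRACTION,
) -> pd.DataFrame:
    """Preprocess, score, and normalize one subject's trace for one phase.

    Returns a per-event table with raw and normalized amplitudes plus
    the subject-level responder flag and response fraction.
    """
    pre = preprocess(trace, cutoff_hz, n_coefficients, window_samples)
    table = score_events(pre, phase=phase, window=window, floor=floor)
    scored = normalize_subject(table["raw"].to_numpy())
    table = table.copy()
    table["normalized"] = scored.normalized
    table["responder"] = classify_responder_fraction(
        scored.response_fraction, min_fraction
    )
    table["response_fraction"] = scored.response_fraction
    table["phase"] = phase
    return table
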
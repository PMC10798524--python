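"""The numbered analysis models, paired tests, and effect translations.

The behavioral analysis is a conservative two-step procedure.  Step one
fits the current-trial model (model 1: risky gain, safe amount, and the
run's EV-level "magnitude", with correlated subject slopes on the first
two).  Its linear predictions — computed prior to the link function —
are then frozen into every later behavioral model through the offset
argument, so the context regressors (previous outcome, EV shifts,
cumulative earnings, linear expectation, and interactions) can only
explain variance the current-trial model left over.  Any shared variance
goes to the current-trial terms, making the context estimates lower
bounds.

SCR models are linear mixed models on sqrt/max-normalized response
amplitudes, fitted to responder subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .glmm import (
    FitResult,
    ModelSpec,
    fit_binomial_glmm,
    fit_linear_mixed,
    fit_model,
    linear_predictions,
)

__all__ = [
    "MODEL_SPECS",
    "SuiteReport",
    "two_step",
    "run_behavior_suite",
    "run_scr_suite",
    "attach_scr",
    "paired_category_tests",
    "effect_to_probability",
    "compare_aic",
]

OFFSET_COL = "offset_m1"

_B = dict(family="binomial", offset=OFFSET_COL, random=("1",))

#: every printed model formula, one-to-one
MODEL_SPECS: dict[str, ModelSpec] = {
    "1": ModelSpec(
        "choice", ("riskygain", "safe", "magnitude"),
        random=("riskygain", "safe"), family="binomial", name="1",
    ),
    "2": ModelSpec("choice", ("prev_outcome",), name="2", **_B),
    "3a": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "neg_shift"), name="3a", **_B
    ),
    "3b": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "pos_shift_prev"), name="3b", **_B
    ),
    "3c": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "pos_shift:prev_outcome"),
        name="3c", **_B,
    ),
    "4a": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "earnings", "expectation"),
        name="4a", **_B,
    ),
    "4b": ModelSpec(
        "choice",
        ("prev_outcome", "pos_shift", "earnings", "earnings:prev_outcome",
         "expectation"),
        name="4b", **_B,
    ),
    # AIC comparison companions to model 4a (earnings-only / expectations-only)
    "4a_earnings": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "earnings"),
        name="4a_earnings", **_B,
    ),
    "4a_expectation": ModelSpec(
        "choice", ("prev_outcome", "pos_shift", "expectation"),
        name="4a_expectation", **_B,
    ),
    "5a": ModelSpec(
        "scr_outcome", ("1", "outcome"), family="gaussian", name="5a"
    ),
    "5b": ModelSpec(
        "scr_outcome", ("1", "pos_shift"), family="gaussian", name="5b"
    ),
    "5c": ModelSpec(
        "scr_outcome", ("1", "earnings", "expectation"),
        family="gaussian", name="5c",
    ),
    "5d": ModelSpec(
        "scr_outcome", ("1", "earnings", "outcome", "earnings:outcome"),
        family="gaussian", name="5d",
    ),
    "6a": ModelSpec(
        "choice",
        ("prev_outcome", "pos_shift", "earnings", "earnings:prev_outcome",
         "scr_outcome_prev"),
        name="6a", **_B,
    ),
    "6b": ModelSpec(
        "choice",
        ("prev_outcome", "pos_shift", "scr_outcome_prev",
         "scr_outcome_prev:prev_outcome"),
        name="6b", **_B,
    ),
    "7": ModelSpec(
        "scr_decision", ("1", "choice_sym"), family="gaussian", name="7"
    ),
    "8a": ModelSpec(
        "scr_decision",
        ("1", "prev_outcome", "pos_shift", "earnings", "expectation"),
        family="gaussian", name="8a",
    ),
    "8b": ModelSpec(
        "scr_decision", ("1", "pos_shift", "pos_shift_prev"),
        family="gaussian", name="8b",
    ),
    "8c": ModelSpec(
        "choice",
        ("prev_outcome", "pos_shift", "earnings", "earnings:prev_outcome",
         "scr_decision"),
        name="8c", **_B,
    ),
}

BEHAVIOR_MODELS = ("2", "3a", "3b", "3c", "4a", "4b")
SCR_LINEAR_MODELS = ("5a", "5b", "5c", "5d", "7", "8a", "8b")
SCR_CHOICE_MODELS = ("6a", "6b", "8c")


@dataclass
class SuiteReport:
    """Fitted models plus the side analyses mirroring the results table."""

    fits: dict[str, FitResult] = field(default_factory=dict)
    aic_table: pd.DataFrame | None = None
    paired_tests: dict[str, dict] = field(default_factory=dict)
    translations: dict[str, float] = field(default_factory=dict)

    def results_table(self) -> pd.DataFrame:
        rows = []
        for mid, fit in self.fits.items():
            for term in fit.params.index:
                rows.append(
                    {
                        "model": mid,
                        "term": term,
                        "estimate": fit.params[term],
                        "se": fit.bse[term],
                        "z": fit.zvalues[term],
                        "p": fit.pvalues[term],
                        "aic": fit.aic,
                        "n": fit.nobs,
                    }
                )
        return pd.DataFrame(rows)


def two_step(
    features: pd.DataFrame,
    context_spec: ModelSpec,
    include_random: bool = True,
    m1_fit: FitResult | None = None,
) -> tuple[FitResult, FitResult]:
    """Fit model 1, freeze its predictions as an offset, fit the context model.

    ``include_random`` controls whether the offset carries the subject
    random-slope contributions.  The default (True) mirrors the
    reference mixed-model ecosystem, whose per-observation predictions
    include the conditional modes.  Folding the shrunken modes into the
    offset absorbs subject-level variation that overlaps the slowly
    varying global regressors (cumulative earnings, expectation) and
    makes their null tests conservative; pass ``include_random=False``
    for fixed-effects-only offsets, which leave subject heterogeneity to
    step two's own random intercept and keep those Wald tests calibrated.
    """
    df = features.copy()
    if m1_fit is None:
        m1_fit = fit_binomial_glmm(df, MODEL_SPECS["1"])
    df[OFFSET_COL] = linear_predictions(m1_fit, df, include_random=include_random)
    return m1_fit, fit_binomial_glmm(df, context_spec)


def run_behavior_suite(
    features: pd.DataFrame,
    include_random: bool = True,
    model3c_offset: str = "1",
    models: tuple[str, ...] = BEHAVIOR_MODELS + ("4a_earnings", "4a_expectation"),
) -> SuiteReport:
    """Fit model 1, then every requested behavioral model on its offset.

    ``model3c_offset`` may be set to ``"3a"`` to feed model 3c the
    predictions of model 3a instead of model 1's.
    """
    report = SuiteReport()
    df = features.copy()
    m1 = fit_binomial_glmm(df, MODEL_SPECS["1"])
    report.fits["1"] = m1
    df[OFFSET_COL] = linear_predictions(m1, df, include_random=include_random)
    for mid in models:
        if mid == "3c" and model3c_offset == "3a":
            if "3a" not in report.fits:
                report.fits["3a"] = fit_binomial_glmm(df, MODEL_SPECS["3a"])
            alt = df.copy()
            alt[OFFSET_COL] = linear_predictions(
                report.fits["3a"], df, include_random=include_random
            )
            report.fits["3c"] = fit_binomial_glmm(alt, MODEL_SPECS["3c"])
            continue
        report.fits[mid] = fit_binomial_glmm(df, MODEL_SPECS[mid])
    aic_ids = [m for m in ("4a", "4a_earnings", "4a_expectation") if m in report.fits]
    if len(aic_ids) > 1:
        report.aic_table = compare_aic({m: report.fits[m] for m in aic_ids})
    if "2" in report.fits:
        report.translations["prev_outcome_max"] = effect_to_probability(
            float(report.fits["2"].params["prev_outcome"]), 1.0
        )
    if "3a" in report.fits:
        # shift regressors are normalized by the money scale; a +$15 shift
        # corresponds to x = 15 / money_scale ~ 15/68 for the standard design
        report.translations["pos_shift_15"] = effect_to_probability(
            float(report.fits["3a"].params["pos_shift"]), 15.0 / 68.0
        )
    return report


def attach_scr(
    features: pd.DataFrame,
    scored_outcome: pd.DataFrame | None = None,
    scored_decision: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge normalized SCR amplitudes (and responder flags) into the
    feature table; adds lagged outcome-phase SCR for models 6a/6b."""
    df = features.copy()
    if scored_outcome is not None:
        s = scored_outcome.rename(
            columns={"normalized": "scr_outcome", "responder": "responder_outcome"}
        )[["subject", "trial_index", "scr_outcome", "responder_outcome"]]
        df = df.merge(s, on=["subject", "trial_index"], how="left")
        prev = s.copy()
        prev["trial_index"] = prev["trial_index"] + 1
        prev = prev.rename(columns={"scr_outcome": "scr_outcome_prev"})
        df = df.merge(
            prev[["subject", "trial_index", "scr_outcome_prev"]],
            on=["subject", "trial_index"],
            how="left",
        )
    if scored_decision is not None:
        s = scored_decision.rename(
            columns={"normalized": "scr_decision", "responder": "responder_decision"}
        )[["subject", "trial_index", "scr_decision", "responder_decision"]]
        df = df.merge(s, on=["subject", "trial_index"], how="left")
    return df


def run_scr_suite(
    features: pd.DataFrame,
    include_random: bool = True,
    models: tuple[str, ...] = SCR_LINEAR_MODELS + SCR_CHOICE_MODELS,
    m1_fit: FitResult | None = None,
) -> SuiteReport:
    """Fit the SCR models on responder subjects.

    ``features`` must carry the columns produced by :func:`attach_scr`.
    Linear models use outcome-phase (5a-5d) or decision-phase (7, 8a-8b)
    responders; the choice models 6a/6b/8c add SCR regressors to the
    two-step behavioral model and carry the model-1 offset.
    """
    report = SuiteReport()
    need_choice = any(m in SCR_CHOICE_MODELS for m in models)
    df_all = features.copy()
    if need_choice:
        if m1_fit is None:
            m1_fit = fit_binomial_glmm(df_all, MODEL_SPECS["1"])
        df_all[OFFSET_COL] = linear_predictions(
            m1_fit, df_all, include_random=include_random
        )
        report.fits["1"] = m1_fit
    for mid in models:
        spec = MODEL_SPECS[mid]
        flag = (
            "responder_decision"
            if spec.response == "scr_decision" or "scr_decision" in spec.fixed
            else "responder_outcome"
        )
        cols = {spec.response, *_base_columns(spec.fixed)}
        cols.discard("1")
        sub = df_all[df_all.get(flag, False) == True]  # noqa: E712
        sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
        if sub[spec.group].nunique() < 2:
            raise ValueError(
                f"model {mid}: fewer than 2 responder subjects after exclusions"
            )
        try:
            report.fits[mid] = fit_model(sub, spec)
        except Exception as exc:  # annotate with the model id
            raise RuntimeError(f"model {mid} failed: {exc}") from exc
    return report


def _base_columns(terms: tuple[str, ...]) -> set[str]:
    out: set[str] = set()
    for t in terms:
        out.update(t.split(":"))
    return out


def paired_category_tests(
    values: pd.DataFrame,
    category_col: str = "category",
    value_col: str = "value",
    subject_col: str = "subject",
    pairs: list[tuple[str, str]] | None = None,
    wilcoxon_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Paired t-tests (and Wilcoxon signed-rank) on per-subject category means.

    Subjects lacking either category of a pair are dropped from that
    comparison.  The Wilcoxon test uses the exact small-sample null for
    n <= 25 paired differences.
    """
    means = values.pivot_table(
        index=subject_col, columns=category_col, values=value_col, aggfunc="mean"
    )
    cats = list(means.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1 :]]
    out: dict = {"t_tests": {}, "wilcoxon": {}, "per_subject_means": means}
    for a, b in pairs:
        d = means[[a, b]].dropna()
        if len(d) < 2:
            raise ValueError(f"fewer than 2 subjects with both {a!r} and {b!r}")
        diffs = (d[a] - d[b]).to_numpy()
        if np.allclose(diffs, 0.0):
            t_stat, p_val = 0.0, 1.0  # degenerate: identical category means
        else:
            t = stats.ttest_rel(d[a], d[b])
            t_stat, p_val = float(t.statistic), float(t.pvalue)
        out["t_tests"][(a, b)] = {
            "t": t_stat,
            "p": p_val,
            "df": len(d) - 1,
            "n": len(d),
        }
    for a, b in wilcoxon_pairs or []:
        d = means[[a, b]].dropna()
        diffs = (d[a] - d[b]).to_numpy()
        mode = "exact" if len(diffs) <= 25 else "auto"
        w = stats.wilcoxon(diffs, method=mode)
        out["wilcoxon"][(a, b)] = {
            "V": float(w.statistic),
            "p": float(w.pvalue),
            "n": len(diffs),
        }
    return out


def effect_to_probability(beta: float, x: float, baseline: float = 0.5) -> float:
    """Percentage-point change in gamble probability from a logit effect.

    Returns ``100 * (logistic(logit(baseline) + beta * x) - baseline)``,
    e.g. the change relative to indifference (baseline 0.5) produced by a
    regressor value ``x`` on the normalized scale.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must be strictly between 0 and 1")
    return float(100.0 * (special.expit(special.logit(baseline) + beta * x) - baseline))


def compare_aic(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Ascending-AIC ranking with a delta column.

    Refuses to compare fits estimated on differing numbers of
    observations (AIC is only meaningful on identical data).
    """
    n_obs = {mid: f.nobs for mid, f in fits.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"fits use different observation counts: {n_obs}")
    df = pd.DataFrame(
        {
            "model": list(fits),
            "aic": [f.aic for f in fits.values()],
            "llf": [f.llf for f in fits.values()],
            "k": [f.k_params for f in fits.values()],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["tie"] = df["delta_aic"].abs() < 1e-9
    return df
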
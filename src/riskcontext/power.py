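"""Simulation-based power for mixed-model terms.

Power for a term is estimated by repeatedly simulating a cohort from the
generative model, re-running the full two-step estimation (the offset is
re-derived from each simulated dataset), and counting replicates whose
Wald p-value falls below alpha.  The rejection proportion is reported
with an exact Clopper-Pearson binomial interval; 88 rejections in the
default 100 simulations yields [79.98%, 93.64%].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import PopulationConfig, simulate_cohort
from .features import NormalizationScheme, build_cohort_features
from .suite import MODEL_SPECS, two_step
from .task import TaskConfig

__all__ = ["PowerResult", "clopper_pearson", "simulate_power"]


@dataclass(frozen=True)
class PowerResult:
    term: str
    model: str
    alpha: float
    n_sims: int
    n_rejections: int
    n_failures: int
    ci: tuple[float, float]

    @property
    def power(self) -> float:
        return self.n_rejections / self.n_sims

    def format(self) -> str:
        lo, hi = self.ci
        return (
            f"{self.power * 100:.0f}% "
            f"(95% CI = [{lo * 100:.2f}% {hi * 100:.2f}%], "
            f"α = {self.alpha:g})"
        )


def clopper_pearson(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def simulate_power(
    term: str,
    model: str = "2",
    population: PopulationConfig | None = None,
    n_subjects: int = 62,
    task: TaskConfig | None = None,
    alpha: float = 0.05,
    n_sims: int = 100,
    seed: int | None = 0,
    max_failure_fraction: float = 0.10,
    include_random: bool = True,
) -> PowerResult:
    """A-posteriori power for one term of a two-step behavioral model.

    Each replicate draws a fresh cohort (task schedules, subjects,
    choices) from ``population``, re-runs model 1 plus the requested
    context model, and records whether the term's Wald p < alpha.
    Replicates whose fit fails to converge are excluded and counted; more
    than ``max_failure_fraction`` failures aborts.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be at least 20 for a meaningful interval")
    spec = MODEL_SPECS[model]
    if term not in spec.fixed:
        raise ValueError(f"term {term!r} is not in model {model}: {spec.fixed}")
    pop = population or PopulationConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    rejections = 0
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        choice_sets, records = _simulate_full(rng, n_subjects, task, pop)
        feats = build_cohort_features(choice_sets, records)
        try:
            _, fit = two_step(feats, spec, include_random=include_random)
            ok = fit.converged
        except Exception:
            ok = False
        if not ok:
            failures += 1
            if failures > max_failure_fraction * n_sims:
                raise RuntimeError(
                    f"{failures} of {n_sims} replicate fits failed; aborting"
                )
            continue
        if float(fit.pvalues[term]) < alpha:
            rejections += 1
    n_eff = n_sims - failures
    return PowerResult(
        term=term,
        model=model,
        alpha=alpha,
        n_sims=n_eff,
        n_rejections=rejections,
        n_failures=failures,
        ci=clopper_pearson(rejections, n_eff),
    )


def _simulate_full(rng, n_subjects, task, pop):
    choice_sets, records, _, _ = simulate_cohort(
        n_subjects=n_subjects, task=task, population=pop, seed=rng
    )
    return choice_sets, records


def power_from_fit(
    fit,
    data,
    term: str,
    alpha: float = 0.05,
    n_sims: int = 100,
    seed: int | None = 0,
    max_failure_fraction: float = 0.10,
) -> PowerResult:
    """Frozen-offset power: parametric bootstrap from a fitted context model.

    Mirrors the a-posteriori approach of simulating responses from the
    fitted model itself — the stage-one offset stays fixed as data, new
    subject random effects are drawn from the fitted covariance, binary
    responses are re-simulated, and the same model is refitted.  This
    answers "how often would this fitted effect be detected?", which is a
    far more optimistic question than re-running the whole two-step
    pipeline against a generative effect of the same size (stage one then
    re-absorbs most of a small context signal).
    """
    import pandas as pd
    from scipy import special

    from .glmm import design_matrix, fit_binomial_glmm

    if n_sims < 20:
        raise ValueError("n_sims must be at least 20 for a meaningful interval")
    spec = fit.spec
    if spec.family != "binomial":
        raise ValueError("power_from_fit supports binomial context models")
    if term not in spec.fixed:
        raise ValueError(f"term {term!r} is not in the fitted model: {spec.fixed}")
    df = data.copy().reset_index(drop=True)
    X = design_matrix(df, spec.fixed)
    Z = design_matrix(df, spec.random)
    offset = (
        df[spec.offset].to_numpy(dtype=float) if spec.offset else np.zeros(len(df))
    )
    eta_fixed = offset + (X @ fit.params.to_numpy() if X.shape[1] else 0.0)
    codes, labels = pd.factorize(df[spec.group], sort=True)
    chol = np.linalg.cholesky(
        fit.re_cov.to_numpy() + 1e-12 * np.eye(len(fit.re_cov))
    )
    rng_master = np.random.SeedSequence(seed)
    rejections = failures = 0
    for child in rng_master.spawn(n_sims):
        rng = np.random.default_rng(child)
        b = rng.standard_normal((len(labels), Z.shape[1])) @ chol.T
        eta = eta_fixed + np.einsum("nq,nq->n", Z, b[codes])
        sim = df.copy()
        sim[spec.response] = (
            rng.random(len(df)) < special.expit(eta)
        ).astype(float)
        try:
            refit = fit_binomial_glmm(sim, spec)
            ok = refit.converged
        except Exception:
            ok = False
        if not ok:
            failures += 1
            if failures > max_failure_fraction * n_sims:
                raise RuntimeError(
                    f"{failures} of {n_sims} replicate fits failed; aborting"
                )
            continue
        if float(refit.pvalues[term]) < alpha:
            rejections += 1
    n_eff = n_sims - failures
    return PowerResult(
        term=term,
        model=spec.name or spec.formula(),
        alpha=alpha,
        n_sims=n_eff,
        n_rejections=rejections,
        n_failures=failures,
        ci=clopper_pearson(rejections, n_eff),
    )
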
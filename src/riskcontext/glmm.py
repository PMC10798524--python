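"""Mixed-effects estimation with per-observation offsets.

Two families are supported, matching the analysis suite's needs:

* ``binomial`` (logit link) with subject-level random effects — either a
  random intercept or correlated random slopes — estimated by maximizing
  the Laplace-approximated marginal likelihood.  A fixed offset column
  enters the linear predictor with coefficient 1, which is what the
  two-step procedure uses to freeze the first-stage model.
* ``gaussian`` (identity link) with a subject random intercept, fitted
  by REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
  A gaussian offset is handled exactly by subtracting it from the
  response.

Wald tests (normal reference) are reported for every fixed effect, and
``aic = -2 llf + 2 k`` counts both fixed effects and free covariance
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sstats

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_binomial_glmm",
    "fit_linear_mixed",
    "fit_model",
    "linear_predictions",
]


class RankDeficientError(ValueError):
    """The fixed-effects design matrix is not full column rank."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed`` and ``random`` are tuples of column names; the literal
    ``"1"`` denotes an intercept and ``"a:b"`` a product of two columns.
    ``random=None`` means no random effects (pooled fit); ``random=("1",)``
    a subject random intercept; e.g. ``random=("riskygain", "safe")``
    correlated slopes without an intercept.  ``offset`` names a column
    that enters the linear predictor with coefficient fixed at 1.
    """

    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] | None = ("1",)
    group: str = "subject"
    offset: str | None = None
    family: str = "binomial"
    name: str = ""

    def formula(self) -> str:
        """Render as lme4-style pseudo-code."""
        fn = "glmer" if self.family == "binomial" else "lmer"
        rhs = " + ".join(self.fixed) if self.fixed else ""
        if "1" not in self.fixed:
            rhs = "0 + " + rhs if rhs else "0"
        if self.random is not None:
            re_terms = " + ".join(self.random)
            if "1" not in self.random:
                re_terms = "0 + " + re_terms
            rhs += f" + ({re_terms} | {self.group})"
        extra = ', family = "binomial"' if self.family == "binomial" else ""
        if self.offset:
            extra += f", offset = {self.offset}"
        return f"{fn}({self.response} ~ {rhs}{extra})"

    @classmethod
    def parse(cls, formula: str, group: str = "subject", name: str = "") -> "ModelSpec":
        """Parse lme4-style pseudo-code back into a spec.

        Accepts the same grammar :meth:`formula` emits, e.g.
        ``glmer(choice ~ 0 + x + (1 | subject), family = "binomial",
        offset = off)`` or ``lmer(y ~ 1 + x + (1 | subject))``.
        """
        import re

        m = re.fullmatch(r"\s*(glmer|lmer)\((.*)\)\s*", formula, re.DOTALL)
        if not m:
            raise ValueError(f"cannot parse model formula: {formula!r}")
        fn, body = m.group(1), m.group(2)
        family = "binomial" if fn == "glmer" else "gaussian"
        offset = None
        fam_m = re.search(r',\s*family\s*=\s*"(\w+)"', body)
        if fam_m:
            family = fam_m.group(1)
            body = body[: fam_m.start()] + body[fam_m.end():]
        off_m = re.search(r",\s*offset\s*=\s*([\w.]+)", body)
        if off_m:
            offset = off_m.group(1)
            body = body[: off_m.start()] + body[off_m.end():]
        if "~" not in body:
            raise ValueError(f"no response in model formula: {formula!r}")
        response, rhs = (s.strip() for s in body.split("~", 1))
        random: tuple[str, ...] | None = None
        re_m = re.search(r"\(\s*([^|]+)\|\s*([\w.]+)\s*\)", rhs)
        if re_m:
            re_terms = [t.strip() for t in re_m.group(1).split("+")]
            re_terms = [t for t in re_terms if t not in ("", "0")]
            random = tuple(re_terms)
            group = re_m.group(2)
            rhs = rhs[: re_m.start()] + rhs[re_m.end():]
        fixed = tuple(
            t for t in (s.strip() for s in rhs.split("+")) if t not in ("", "0")
        )
        return cls(
            response=response, fixed=fixed, random=random, group=group,
            offset=offset, family=family, name=name,
        )


@dataclass
class FitResult:
    """Coefficients, Wald statistics, variance components, fit indices."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    nobs: int
    ngroups: int
    k_params: int
    converged: bool
    grad_norm: float = np.nan
    re_cov: pd.DataFrame | None = None
    re_modes: pd.DataFrame | None = None
    resid_var: float | None = None
    cov_params: pd.DataFrame | None = None
    boundary: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "model": self.spec.name or self.spec.formula(),
            "formula": self.spec.formula(),
            "family": self.spec.family,
            "coefficients": {
                term: {
                    "estimate": float(self.params[term]),
                    "se": float(self.bse[term]),
                    "z": float(self.zvalues[term]),
                    "p": float(self.pvalues[term]),
                }
                for term in self.params.index
            },
            "random_effect_covariance": (
                self.re_cov.to_dict() if self.re_cov is not None else None
            ),
            "loglik": self.llf,
            "aic": self.aic,
            "nobs": self.nobs,
            "ngroups": self.ngroups,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term == "1":
        return np.ones(len(data))
    if ":" in term:
        a, b = term.split(":", 1)
        return _column(data, a) * _column(data, b)
    if term not in data.columns:
        raise KeyError(f"column {term!r} not found in data")
    return data[term].to_numpy(dtype=float)


def design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    if not terms:
        return np.empty((len(data), 0))
    return np.column_stack([_column(data, t) for t in terms])


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name columns involved in the collinearity via QR pivot diagnostics
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(d)) if d[i] < 1e-8 * d[0]]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear columns include {bad}"
        )


# ---------------------------------------------------------------------------
# covariance parameterization: log-SDs plus atanh correlations (q <= 2)
# ---------------------------------------------------------------------------

def _theta_to_cov(theta: np.ndarray, q: int) -> np.ndarray:
    sds = np.exp(theta[:q])
    if q == 1:
        return np.array([[sds[0] ** 2]])
    rho = np.tanh(theta[q])
    c = rho * sds[0] * sds[1]
    return np.array([[sds[0] ** 2, c], [c, sds[1] ** 2]])


def _n_theta(q: int) -> int:
    return q + q * (q - 1) // 2


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _LaplaceProblem:
    """Marginal likelihood machinery for one binomial GLMM fit.

    Rows are pre-sorted by group so per-subject reductions use
    ``np.add.reduceat``; per-subject Newton mode finding is vectorized
    across subjects (closed-form 1x1 / 2x2 solves).
    """

    def __init__(self, y, X, Z, codes, offset):
        order = np.argsort(codes, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.Z = Z[order]
        self.codes = codes[order]
        self.offset = offset[order]
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.m = int(self.codes.max()) + 1
        self.starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(self.codes)) + 1]
        )
        self.b = np.zeros((self.m, self.q))

    # -- inner problem ----------------------------------------------------
    def _group_sum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts, axis=0)

    def _penalized(self, eta: np.ndarray, b: np.ndarray, Sinv: np.ndarray) -> np.ndarray:
        per_obs = self.y * eta - _softplus(eta)
        return self._group_sum(per_obs) - 0.5 * np.einsum(
            "mq,qr,mr->m", b, Sinv, b
        )

    def _eta(self, eta_fixed: np.ndarray, b: np.ndarray) -> np.ndarray:
        return eta_fixed + np.einsum("nq,nq->n", self.Z, b[self.codes])

    def find_modes(self, beta, Sinv, max_iter=200, tol=1e-9):
        eta_fixed = (self.X @ beta if self.p else 0.0) + self.offset
        b = self.b.copy()
        eta = self._eta(eta_fixed, b)
        obj = self._penalized(eta, b, Sinv)
        for _ in range(max_iter):
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            g = self._group_sum(self.Z * (self.y - mu)[:, None]) - b @ Sinv
            if np.max(np.abs(g)) < tol:
                break
            delta = self._solve(w, g, Sinv)
            # damped Newton: halve per-subject steps that decrease the
            # penalized objective (rare; logistic overshoot at extreme eta)
            step = np.ones(self.m)
            for _ in range(40):
                b_new = b + step[:, None] * delta
                eta_new = self._eta(eta_fixed, b_new)
                obj_new = self._penalized(eta_new, b_new, Sinv)
                worse = obj_new < obj - 1e-12
                if not worse.any():
                    break
                step[worse] *= 0.5
            b, eta, obj = b_new, eta_new, obj_new
        self.b = b
        mu = special.expit(eta)
        return b, eta, mu * (1.0 - mu)

    def _solve(self, w, g, Sinv):
        if self.q == 1:
            h = self._group_sum(w * self.Z[:, 0] ** 2)[:, None] + Sinv[0, 0]
            return g / h
        z1, z2 = self.Z[:, 0], self.Z[:, 1]
        s11 = self._group_sum(w * z1 * z1) + Sinv[0, 0]
        s12 = self._group_sum(w * z1 * z2) + Sinv[0, 1]
        s22 = self._group_sum(w * z2 * z2) + Sinv[1, 1]
        det = s11 * s22 - s12 * s12
        d1 = (s22 * g[:, 0] - s12 * g[:, 1]) / det
        d2 = (-s12 * g[:, 0] + s11 * g[:, 1]) / det
        return np.column_stack([d1, d2])

    # -- Laplace marginal log-likelihood ----------------------------------
    def marginal_nll(self, x: np.ndarray) -> float:
        beta = x[: self.p]
        Sigma = _theta_to_cov(x[self.p :], self.q)
        Sinv = np.linalg.inv(Sigma)
        sign, logdet_S = np.linalg.slogdet(Sigma)
        b, eta, w = self.find_modes(beta, Sinv)
        ll = float(np.sum(self.y * eta - _softplus(eta)))
        ll -= 0.5 * float(np.einsum("mq,qr,mr->", b, Sinv, b))
        ll -= 0.5 * self.m * logdet_S
        if self.q == 1:
            h = self._group_sum(w * self.Z[:, 0] ** 2) + Sinv[0, 0]
            ll -= 0.5 * float(np.sum(np.log(h)))
        else:
            z1, z2 = self.Z[:, 0], self.Z[:, 1]
            s11 = self._group_sum(w * z1 * z1) + Sinv[0, 0]
            s12 = self._group_sum(w * z1 * z2) + Sinv[0, 1]
            s22 = self._group_sum(w * z2 * z2) + Sinv[1, 1]
            ll -= 0.5 * float(np.sum(np.log(s11 * s22 - s12 * s12)))
        return -ll


def _pooled_logistic(y, X, offset, max_iter=50, tol=1e-10):
    """Plain logistic MLE with offset (Newton with a small ridge guard)."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = special.expit(eta)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) < tol:
            break
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(p)
        beta = beta + np.linalg.solve(H, g)
    return beta


def fit_binomial_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    maxiter: int = 500,
    gtol: float = 1e-6,
) -> FitResult:
    """Fit a binomial-logit mixed model by Laplace-approximated ML.

    Deterministic given data and starting values (pooled-logistic start
    for the fixed effects).  Standard errors come from the observed
    information in the fixed effects at the optimum, with covariance
    parameters held at their estimates — the convention behind printed
    beta/SE/p triplets.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be binary 0/1 with no NaNs")
    X = design_matrix(data, spec.fixed)
    _check_rank(X, spec.fixed)
    offset = (
        data[spec.offset].to_numpy(dtype=float)
        if spec.offset
        else np.zeros(len(data))
    )

    if spec.random is None:
        return _fit_pooled_glm(data, spec, y, X, offset)

    labels, codes = _group_codes(data, spec.group)
    if len(labels) < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    Z = design_matrix(data, spec.random)
    q = Z.shape[1]
    if q not in (1, 2):
        raise NotImplementedError("random structures with more than 2 terms")

    prob = _LaplaceProblem(y, X, Z, codes, offset)
    p = prob.p
    beta0 = _pooled_logistic(prob.y, prob.X, prob.offset) if p else np.empty(0)
    theta0 = np.concatenate([np.full(q, np.log(0.5)), np.zeros(_n_theta(q) - q)])
    x0 = np.concatenate([beta0, theta0])
    bounds = [(None, None)] * p + [(-10.0, 4.0)] * q + [(-4.0, 4.0)] * (
        _n_theta(q) - q
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            prob.marginal_nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
    xhat = res.x
    beta_hat, theta_hat = xhat[:p], xhat[p:]
    llf = -prob.marginal_nll(xhat)
    Sigma = _theta_to_cov(theta_hat, q)
    boundary = bool(np.any(np.exp(theta_hat[:q]) < 1e-3))

    # Wald covariance: observed information in beta at (beta_hat, theta_hat)
    if p:
        H = _beta_hessian(prob, xhat, p)
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        cov = np.empty((0, 0))
        bse = np.empty(0)

    k = p + _n_theta(q)
    names = list(spec.fixed)
    params = pd.Series(beta_hat, index=names, dtype=float)
    bse_s = pd.Series(bse, index=names, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse_s
    pvals = pd.Series(2 * sstats.norm.sf(np.abs(z)), index=names)
    re_names = list(spec.random)
    modes = pd.DataFrame(prob.b, index=labels, columns=re_names)
    return FitResult(
        spec=spec,
        params=params,
        bse=bse_s,
        zvalues=z,
        pvalues=pvals,
        llf=float(llf),
        aic=float(-2 * llf + 2 * k),
        nobs=len(y),
        ngroups=len(labels),
        k_params=k,
        converged=bool(res.success),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        re_cov=pd.DataFrame(Sigma, index=re_names, columns=re_names),
        re_modes=modes,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        boundary=boundary,
    )


def _beta_hessian(prob: _LaplaceProblem, xhat: np.ndarray, p: int) -> np.ndarray:
    f = prob.marginal_nll
    h = 1e-4 * np.maximum(1.0, np.abs(xhat[:p]))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros_like(xhat)
        ei[i] = h[i]
        for j in range(i, p):
            ej = np.zeros_like(xhat)
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(xhat + ei) - 2 * f(xhat) + f(xhat - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(xhat + ei + ej)
                    - f(xhat + ei - ej)
                    - f(xhat - ei + ej)
                    + f(xhat - ei - ej)
                ) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _group_codes(data: pd.DataFrame, group: str):
    codes, labels = pd.factorize(data[group], sort=True)
    return list(labels), codes.astype(np.int64)


def _fit_pooled_glm(data, spec, y, X, offset) -> FitResult:
    """Degenerate limit: no random effects -> ordinary logistic ML."""
    beta = _pooled_logistic(y, X, offset)
    eta = (X @ beta if X.shape[1] else 0.0) + offset
    mu = special.expit(eta)
    llf = float(np.sum(y * eta - _softplus(eta)))
    w = mu * (1 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    bse = np.sqrt(np.diag(cov))
    names = list(spec.fixed)
    params = pd.Series(beta, index=names)
    bse_s = pd.Series(bse, index=names)
    z = params / bse_s
    k = len(names)
    return FitResult(
        spec=spec,
        params=params,
        bse=bse_s,
        zvalues=z,
        pvalues=pd.Series(2 * sstats.norm.sf(np.abs(z)), index=names),
        llf=llf,
        aic=-2 * llf + 2 * k,
        nobs=len(y),
        ngroups=data[spec.group].nunique() if spec.group in data else 1,
        k_params=k,
        converged=True,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
    )


def fit_linear_mixed(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Gaussian mixed model (subject random intercept) by REML.

    Backed by statsmodels MixedLM; Wald normal p-values, matching the
    binomial engine's convention.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    if spec.family != "gaussian":
        raise ValueError("fit_linear_mixed requires a gaussian family spec")
    if spec.random != ("1",):
        raise NotImplementedError("gaussian fits support a random intercept only")
    y = data[spec.response].to_numpy(dtype=float)
    if spec.offset:  # identity link: a fixed offset is an exact shift
        y = y - data[spec.offset].to_numpy(dtype=float)
    X = design_matrix(data, spec.fixed)
    _check_rank(X, spec.fixed)
    groups = data[spec.group].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    names = list(spec.fixed)
    boundary = bool(np.asarray(res.cov_re)[0, 0] < 1e-8 * max(res.scale, 1e-12))
    if boundary:
        # at the boundary the model is ordinary least squares; statsmodels
        # is numerically unstable there, so report the exact OLS solution
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        params = pd.Series(np.asarray(ols.params), index=names)
        bse = pd.Series(np.asarray(ols.bse), index=names)
    else:
        params = pd.Series(np.asarray(res.fe_params), index=names)
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
    z = params / bse
    pvals = pd.Series(2 * sstats.norm.sf(np.abs(z)), index=names)
    k = len(names) + 2  # random-intercept variance + residual variance
    llf = float(res.llf)
    try:
        modes = pd.DataFrame(
            {g: v.to_numpy() for g, v in res.random_effects.items()}
        ).T
    except (np.linalg.LinAlgError, ValueError):
        # variance at the boundary: best predictions are identically zero
        modes = pd.DataFrame(
            np.zeros((len(np.unique(groups)), 1)), index=np.unique(groups)
        )
    modes.columns = ["1"]
    return FitResult(
        spec=spec,
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=pvals,
        llf=llf,
        aic=float(-2 * llf + 2 * k),
        nobs=len(y),
        ngroups=len(modes),
        k_params=k,
        converged=bool(res.converged),
        re_cov=pd.DataFrame(np.asarray(res.cov_re), index=["1"], columns=["1"]),
        re_modes=modes,
        resid_var=float(res.scale),
        boundary=boundary,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Dispatch on family."""
    if spec.family == "binomial":
        return fit_binomial_glmm(data, spec)
    if spec.family == "gaussian":
        return fit_linear_mixed(data, spec)
    raise ValueError(f"unknown family {spec.family!r}")


def linear_predictions(
    fit: FitResult, data: pd.DataFrame, include_random: bool = True
) -> np.ndarray:
    """Per-observation linear predictor eta = offset + X beta (+ Z b).

    These are the values fed to downstream models through the offset
    argument (computed prior to the link function).
    """
    spec = fit.spec
    X = design_matrix(data, spec.fixed)
    eta = X @ fit.params.to_numpy() if X.shape[1] else np.zeros(len(data))
    if spec.offset:
        eta = eta + data[spec.offset].to_numpy(dtype=float)
    if include_random and fit.re_modes is not None:
        Z = design_matrix(data, spec.random)
        groups = data[spec.group]
        unseen = set(groups.unique()) - set(fit.re_modes.index)
        if unseen:
            raise ValueError(f"subjects not present in the fit: {sorted(unseen)}")
        B = fit.re_modes.loc[groups].to_numpy()
        eta = eta + np.einsum("nq,nq->n", Z, B)
    return eta
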
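"""Mixed-model engine: Laplace likelihood, offsets, recovery, Wald output."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from riskcontext.glmm import (
    ModelSpec,
    RankDeficientError,
    fit_binomial_glmm,
    fit_linear_mixed,
    linear_predictions,
)

from oracles import quadrature_marginal_loglik


def simulate_logistic(seed, n_sub, n_per, beta=1.0, sd=0.5, offset=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        b = rng.normal(0, sd)
        x = rng.normal(size=n_per)
        eta = beta * x + b
        if offset is not None:
            eta = eta + offset
        y = (rng.random(n_per) < special.expit(eta)).astype(float)
        rows += [{"subject": s, "x": xi, "y": yi} for xi, yi in zip(x, y)]
    return pd.DataFrame(rows)


SPEC_RI = ModelSpec("y", ("x",), random=("1",))


class TestBinomialEngine:
    def test_pooled_limit_matches_plain_logistic(self):
        df = simulate_logistic(0, 10, 40, sd=0.0)
        pooled = fit_binomial_glmm(df, ModelSpec("y", ("x",), random=None))
        import statsmodels.api as sm

        ref = sm.GLM(df["y"], df[["x"]], family=sm.families.Binomial()).fit()
        assert pooled.params["x"] == pytest.approx(ref.params["x"], abs=1e-6)
        assert pooled.bse["x"] == pytest.approx(ref.bse["x"], rel=1e-4)

    def test_laplace_matches_quadrature_oracle(self):
        """3 subjects x 20 trials, modest random-intercept variance."""
        from riskcontext.glmm import _LaplaceProblem, design_matrix

        sd = 0.2
        df = simulate_logistic(3, 3, 20, sd=sd)
        prob = _LaplaceProblem(
            df["y"].to_numpy(float),
            design_matrix(df, ("x",)),
            design_matrix(df, ("1",)),
            df["subject"].to_numpy(np.int64),
            np.zeros(len(df)),
        )
        lap = -prob.marginal_nll(np.array([1.0, np.log(sd)]))
        quad = quadrature_marginal_loglik(df, beta=1.0, sd=sd)
        assert lap == pytest.approx(quad, abs=1e-3)

    def test_laplace_error_shrinks_with_variance(self):
        """The Gaussian approximation improves as the random-effect
        variance decreases (error roughly O(sd^4))."""
        from riskcontext.glmm import _LaplaceProblem, design_matrix

        df = simulate_logistic(5, 3, 20, sd=0.4)
        prob = _LaplaceProblem(
            df["y"].to_numpy(float),
            design_matrix(df, ("x",)),
            design_matrix(df, ("1",)),
            df["subject"].to_numpy(np.int64),
            np.zeros(len(df)),
        )
        errs = []
        for sd in (0.5, 0.3, 0.15):
            lap = -prob.marginal_nll(np.array([1.0, np.log(sd)]))
            errs.append(abs(lap - quadrature_marginal_loglik(df, 1.0, sd)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 5e-4

    def test_parameter_recovery_random_intercept(self):
        """50 subjects x 100 trials from beta=1, sd=0.5: estimates center
        on truth within Monte-Carlo error across seeds."""
        betas, sds = [], []
        for seed in range(20):
            df = simulate_logistic(100 + seed, 50, 100)
            fit = fit_binomial_glmm(df, SPEC_RI)
            assert fit.converged
            betas.append(float(fit.params["x"]))
            sds.append(float(np.sqrt(fit.re_cov.values[0, 0])))
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 1.0) < 3 * mc_se
        mc_se_sd = np.std(sds, ddof=1) / np.sqrt(len(sds))
        assert abs(np.mean(sds) - 0.5) < 4 * mc_se_sd  # Laplace mildly biased

    def test_offset_enters_with_coefficient_one(self):
        rng = np.random.default_rng(7)
        df = simulate_logistic(7, 20, 60, beta=0.8, sd=0.4)
        df["known"] = rng.normal(size=len(df))
        # simulate again including the known offset
        eta = 0.8 * df["x"].to_numpy() + df["known"].to_numpy()
        b = rng.normal(0, 0.4, size=20)
        eta = eta + b[df["subject"].to_numpy()]
        df["y"] = (rng.random(len(df)) < special.expit(eta)).astype(float)
        with_off = fit_binomial_glmm(
            df, ModelSpec("y", ("x",), random=("1",), offset="known")
        )
        assert with_off.params["x"] == pytest.approx(0.8, abs=3 * with_off.bse["x"])
        # the offset is not estimated: refit treating it as a regressor
        as_reg = fit_binomial_glmm(df, ModelSpec("y", ("x", "known"), random=("1",)))
        assert as_reg.params["known"] == pytest.approx(1.0, abs=3 * as_reg.bse["known"])

    def test_offset_only_model_reproduces_offset(self):
        df = simulate_logistic(9, 10, 50, beta=1.0, sd=0.3)
        fit0 = fit_binomial_glmm(df, SPEC_RI)
        df["eta"] = linear_predictions(fit0, df, include_random=True)
        refit = fit_binomial_glmm(
            df, ModelSpec("y", (), random=("1",), offset="eta")
        )
        pred = linear_predictions(refit, df, include_random=True)
        # no free fixed effects: predictions = offset + (near-zero modes)
        assert np.abs(pred - df["eta"].to_numpy()).max() < 0.05

    def test_include_random_flag_matters_only_with_variance(self):
        df = simulate_logistic(2, 10, 50, sd=0.0)
        fit = fit_binomial_glmm(df, SPEC_RI)
        assert fit.boundary  # estimated variance collapses for these data
        a = linear_predictions(fit, df, include_random=True)
        b = linear_predictions(fit, df, include_random=False)
        assert np.abs(a - b).max() < 1e-3

    def test_aic_identity(self):
        df = simulate_logistic(13, 10, 50)
        fit = fit_binomial_glmm(df, SPEC_RI)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.k_params)
        assert fit.k_params == 2  # one slope + one variance

    def test_rank_deficiency_names_columns(self):
        df = simulate_logistic(15, 5, 30)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(RankDeficientError, match="x2|x"):
            fit_binomial_glmm(df, ModelSpec("y", ("x", "x2"), random=("1",)))

    def test_non_binary_response_rejected(self):
        df = simulate_logistic(16, 5, 30)
        df.loc[0, "y"] = 0.5
        with pytest.raises(ValueError, match="binary"):
            fit_binomial_glmm(df, SPEC_RI)

    def test_correlated_random_slopes(self):
        rng = np.random.default_rng(21)
        rows = []
        for s in range(40):
            d = rng.multivariate_normal([0, 0], [[1.0, -0.5], [-0.5, 1.0]])
            x1, x2 = rng.normal(size=(2, 80))
            eta = (1.0 + d[0]) * x1 + (-0.5 + d[1]) * x2
            y = (rng.random(80) < special.expit(eta)).astype(float)
            rows += [
                {"subject": s, "x1": a, "x2": b, "y": yy}
                for a, b, yy in zip(x1, x2, y)
            ]
        df = pd.DataFrame(rows)
        fit = fit_binomial_glmm(
            df, ModelSpec("y", ("x1", "x2"), random=("x1", "x2"))
        )
        assert fit.converged
        assert fit.params["x1"] == pytest.approx(1.0, abs=3 * fit.bse["x1"])
        assert fit.params["x2"] == pytest.approx(-0.5, abs=3 * fit.bse["x2"])
        v = np.diag(fit.re_cov.values)
        assert np.all(v > 0.3) and np.all(v < 2.5)

    def test_two_step_matches_joint_on_orthogonal_design(self):
        """When the first-stage and context regressors are orthogonal by
        construction, freezing stage one as an offset changes nothing."""
        rng = np.random.default_rng(31)
        rows = []
        for s in range(40):
            b = rng.normal(0, 0.3)
            x = np.tile([-1.0, 1.0], 40)          # stage-one regressor
            z = np.repeat([-1.0, 1.0], 40)        # context regressor, orthogonal
            rng.shuffle(z)
            eta = 0.9 * x + 0.6 * z + b
            y = (rng.random(80) < special.expit(eta)).astype(float)
            rows += [
                {"subject": s, "x": xi, "z": zi, "y": yi}
                for xi, zi, yi in zip(x, z, y)
            ]
        df = pd.DataFrame(rows)
        joint = fit_binomial_glmm(df, ModelSpec("y", ("x", "z"), random=("1",)))
        stage1 = fit_binomial_glmm(df, ModelSpec("y", ("x",), random=("1",)))
        df["off"] = linear_predictions(stage1, df, include_random=True)
        stage2 = fit_binomial_glmm(
            df, ModelSpec("y", ("z",), random=("1",), offset="off")
        )
        se = float(joint.bse["z"])
        assert float(stage2.params["z"]) == pytest.approx(
            float(joint.params["z"]), abs=2 * se
        )


class TestLinearMixed:
    def _toy(self, seed=0, slope=0.12, sd_sub=0.3, sd_eps=0.2, n_sub=40, n_per=50):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            b = rng.normal(0, sd_sub)
            x = rng.normal(size=n_per)
            y = 1.0 + slope * x + b + rng.normal(0, sd_eps, n_per)
            rows += [{"subject": s, "x": xi, "y": yi} for xi, yi in zip(x, y)]
        return pd.DataFrame(rows)

    SPEC = ModelSpec("y", ("1", "x"), random=("1",), family="gaussian")

    def test_zero_between_variance_matches_ols(self):
        df = self._toy(seed=4, sd_sub=0.0, n_sub=10, n_per=30)
        fit = fit_linear_mixed(df, self.SPEC)
        import statsmodels.api as sm

        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-4)
        assert fit.boundary

    def test_balanced_intercept_is_grand_mean(self):
        df = pd.DataFrame(
            {
                "subject": np.repeat([0, 1], 10),
                "y": np.concatenate([np.full(10, 2.0), np.full(10, 4.0)]),
            }
        )
        fit = fit_linear_mixed(
            df, ModelSpec("y", ("1",), random=("1",), family="gaussian")
        )
        assert fit.params["1"] == pytest.approx(3.0, abs=1e-6)

    def test_slope_recovery_across_seeds(self):
        ests = []
        for seed in range(20):
            fit = fit_linear_mixed(self._toy(seed=seed, n_sub=40, n_per=100), self.SPEC)
            ests.append(float(fit.params["x"]))
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.12) < 3 * mc_se

    def test_gaussian_offset_is_exact_shift(self):
        df = self._toy(seed=3)
        df["off"] = 5.0
        spec = ModelSpec(
            "y", ("1", "x"), random=("1",), family="gaussian", offset="off"
        )
        base = fit_linear_mixed(df, self.SPEC)
        shifted = fit_linear_mixed(df, spec)
        assert shifted.params["1"] == pytest.approx(base.params["1"] - 5.0, abs=1e-8)
        assert shifted.params["x"] == pytest.approx(base.params["x"], abs=1e-8)
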
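"""Model suite: formula conformance, translations, AIC, paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riskcontext as rc
from riskcontext.glmm import FitResult, ModelSpec
from riskcontext.suite import (
    MODEL_SPECS,
    compare_aic,
    effect_to_probability,
    paired_category_tests,
    run_behavior_suite,
)

from oracles import exact_wilcoxon_p

# lme4-style pseudo-code for every model, with field names substituted
EXPECTED_FORMULAS = {
    "1": 'glmer(choice ~ 0 + riskygain + safe + magnitude + '
         '(0 + riskygain + safe | subject), family = "binomial")',
    "2": 'glmer(choice ~ 0 + prev_outcome + (1 | subject), '
         'family = "binomial", offset = offset_m1)',
    "3a": 'glmer(choice ~ 0 + prev_outcome + pos_shift + neg_shift + '
          '(1 | subject), family = "binomial", offset = offset_m1)',
    "3b": 'glmer(choice ~ 0 + prev_outcome + pos_shift + pos_shift_prev + '
          '(1 | subject), family = "binomial", offset = offset_m1)',
    "3c": 'glmer(choice ~ 0 + prev_outcome + pos_shift + '
          'pos_shift:prev_outcome + (1 | subject), family = "binomial", '
          'offset = offset_m1)',
    "4a": 'glmer(choice ~ 0 + prev_outcome + pos_shift + earnings + '
          'expectation + (1 | subject), family = "binomial", '
          'offset = offset_m1)',
    "4b": 'glmer(choice ~ 0 + prev_outcome + pos_shift + earnings + '
          'earnings:prev_outcome + expectation + (1 | subject), '
          'family = "binomial", offset = offset_m1)',
    "5a": 'lmer(scr_outcome ~ 1 + outcome + (1 | subject))',
    "5b": 'lmer(scr_outcome ~ 1 + pos_shift + (1 | subject))',
    "5c": 'lmer(scr_outcome ~ 1 + earnings + expectation + (1 | subject))',
    "5d": 'lmer(scr_outcome ~ 1 + earnings + outcome + earnings:outcome + '
          '(1 | subject))',
    "6a": 'glmer(choice ~ 0 + prev_outcome + pos_shift + earnings + '
          'earnings:prev_outcome + scr_outcome_prev + (1 | subject), '
          'family = "binomial", offset = offset_m1)',
    "6b": 'glmer(choice ~ 0 + prev_outcome + pos_shift + scr_outcome_prev + '
          'scr_outcome_prev:prev_outcome + (1 | subject), '
          'family = "binomial", offset = offset_m1)',
    "7": 'lmer(scr_decision ~ 1 + choice_sym + (1 | subject))',
    "8a": 'lmer(scr_decision ~ 1 + prev_outcome + pos_shift + earnings + '
          'expectation + (1 | subject))',
    "8b": 'lmer(scr_decision ~ 1 + pos_shift + pos_shift_prev + '
          '(1 | subject))',
    "8c": 'glmer(choice ~ 0 + prev_outcome + pos_shift + earnings + '
          'earnings:prev_outcome + scr_decision + (1 | subject), '
          'family = "binomial", offset = offset_m1)',
}


def test_every_model_renders_its_formula():
    for mid, expected in EXPECTED_FORMULAS.items():
        assert MODEL_SPECS[mid].formula() == expected


def test_formula_grammar_round_trips():
    for mid, spec in MODEL_SPECS.items():
        parsed = ModelSpec.parse(spec.formula(), name=spec.name)
        assert parsed == spec, mid
    # serialization carries the coefficient table
    import json

    from riskcontext.glmm import fit_binomial_glmm

    import riskcontext as rc

    sets, recs, _, norm = rc.simulate_cohort(n_subjects=3, seed=2)
    feats = rc.build_cohort_features(sets, recs, norm)
    fit = fit_binomial_glmm(feats, MODEL_SPECS["1"])
    blob = json.dumps(fit.to_dict())
    assert "riskygain" in blob and "aic" in blob


def test_behavioral_models_all_carry_the_stage_one_offset():
    for mid in ("2", "3a", "3b", "3c", "4a", "4b", "6a", "6b", "8c"):
        assert MODEL_SPECS[mid].offset == "offset_m1"
    assert MODEL_SPECS["1"].offset is None


class TestEffectToProbability:
    @pytest.mark.parametrize(
        "beta,x,expected",
        [
            (-0.15, 68 / 68, -3.7),  # maximal previous outcome
            (4.8, 15 / 68, 24.2),    # +$15 positive shift
        ],
    )
    def test_published_translations(self, beta, x, expected):
        got = effect_to_probability(beta, x)
        assert round(got, 1) == expected

    def test_zero_effect_is_zero(self):
        for base in (0.2, 0.5, 0.8):
            assert effect_to_probability(0.0, 1.7, baseline=base) == 0.0

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            effect_to_probability(1.0, 1.0, baseline=1.0)


class TestPairedTests:
    def _frame(self, means_by_subject):
        rows = []
        for s, cats in enumerate(means_by_subject):
            for cat, val in cats.items():
                rows.append({"subject": s, "category": cat, "value": val})
        return pd.DataFrame(rows)

    def test_identical_categories_give_t_zero_p_one(self):
        df = self._frame([{"win": 0.2, "loss": 0.2}, {"win": 0.3, "loss": 0.3},
                          {"win": 0.1, "loss": 0.1}])
        out = paired_category_tests(df, pairs=[("win", "loss")])
        t = out["t_tests"][("win", "loss")]
        assert t["t"] == pytest.approx(0.0)
        assert t["p"] == pytest.approx(1.0)

    def test_mirrored_differences_cancel(self):
        df = self._frame([{"a": 0.5, "b": 0.3}, {"a": 0.3, "b": 0.5}])
        out = paired_category_tests(df, pairs=[("a", "b")])
        assert out["t_tests"][("a", "b")]["t"] == pytest.approx(0.0)

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        diffs = np.array([0.31, -0.12, 0.07, 0.55, -0.02, 0.18])
        rows = []
        for s, d in enumerate(diffs):
            rows.append({"subject": s, "category": "a", "value": 0.5 + d})
            rows.append({"subject": s, "category": "b", "value": 0.5})
        out = paired_category_tests(
            pd.DataFrame(rows), pairs=[], wilcoxon_pairs=[("a", "b")]
        )
        got = out["wilcoxon"][("a", "b")]["p"]
        assert got == pytest.approx(exact_wilcoxon_p(diffs), abs=1e-12)

    def test_subjects_missing_a_category_are_dropped(self):
        df = self._frame(
            [{"a": 0.5, "b": 0.3}, {"a": 0.45, "b": 0.2}, {"a": 0.9}]
        )
        out = paired_category_tests(df, pairs=[("a", "b")])
        assert out["t_tests"][("a", "b")]["n"] == 2


class TestCompareAic:
    def _fake(self, name, llf, k, nobs=100):
        spec = ModelSpec("y", ("x",), name=name)
        s = pd.Series([0.0], index=["x"])
        return FitResult(
            spec=spec, params=s, bse=s, zvalues=s, pvalues=s, llf=llf,
            aic=-2 * llf + 2 * k, nobs=nobs, ngroups=5, k_params=k,
            converged=True,
        )

    def test_tie_detection_and_identity(self):
        fits = {"a": self._fake("a", -50.0, 2), "b": self._fake("b", -50.0, 2)}
        table = compare_aic(fits)
        assert table["tie"].all()
        assert np.allclose(table["aic"], -2 * table["llf"] + 2 * table["k"])

    def test_ranking_ascends(self):
        fits = {
            "worse": self._fake("worse", -60.0, 2),
            "better": self._fake("better", -50.0, 2),
        }
        table = compare_aic(fits)
        assert list(table["model"]) == ["better", "worse"]
        assert table["delta_aic"].iloc[1] == pytest.approx(20.0)

    def test_mismatched_observations_refused(self):
        fits = {"a": self._fake("a", -50.0, 2, nobs=100),
                "b": self._fake("b", -50.0, 2, nobs=90)}
        with pytest.raises(ValueError, match="observation counts"):
            compare_aic(fits)


class TestBehaviorSuite:
    def test_suite_recovers_sign_pattern(self, small_cohort):
        """On the default synthetic cohort, the recovered context effects
        match the generative directions: previous outcome negative,
        positive shift positive, earnings-by-outcome interaction positive."""
        report = run_behavior_suite(small_cohort["features"])
        assert set(report.fits) >= {"1", "2", "3a", "3b", "3c", "4a", "4b"}
        m4b = report.fits["4b"]
        assert m4b.params["prev_outcome"] < 0
        assert m4b.params["pos_shift"] > 0
        assert m4b.params["earnings:prev_outcome"] > 0
        # model 1 current-trial pattern: pro-risky-gain, anti-safe, anti-magnitude
        m1 = report.fits["1"]
        assert m1.params["riskygain"] > 0
        assert m1.params["safe"] < 0
        assert m1.params["magnitude"] < 0
        # AIC companions fitted on identical rows
        assert report.aic_table is not None
        assert set(report.aic_table["model"]) == {
            "4a", "4a_earnings", "4a_expectation"
        }
        # translations computed from the fitted models
        assert report.translations["pos_shift_15"] > 0

    def test_true_model_wins_aic_against_nested_null(self, small_cohort):
        """With a strong earnings effect, the model containing earnings
        outranks the expectation-only companion."""
        report = run_behavior_suite(small_cohort["features"])
        table = report.aic_table.set_index("model")
        assert table.loc["4a", "aic"] <= table.loc["4a_expectation", "aic"] + 2.0
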
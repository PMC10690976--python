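"""Stage logit fits: design construction, MLE agreement with statsmodels,
marginal effects and model-comparison behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import stagevar as sv
from stagevar.models import (
    StageModelSpec,
    StateError,
    build_design,
    covariates_for_level,
    fit_logit,
)
from conftest import make_table


@pytest.fixture(scope="module")
def oracle_sample():
    """Stage-I sample with no rare covariate levels, so the MLE exists and
    the statsmodels row-level fit is a valid independent oracle."""
    from stagevar.simulate import table2_margins

    params = sv.referral_dominated_params(
        6000, n_regions=5, seed=13, mean_visit=0.15,
        covariate_dist={**table2_margins(), "obesity": 0.3, "childbirth": 0.3},
    )
    return sv.select_sample(sv.simulate_claims(params), "I")


class TestBuildDesign:
    def test_crude_two_region_design(self):
        table = make_table([{"region": "A"}, {"region": "B"}, {"region": "B"}])
        X, y, cols = build_design(table, StageModelSpec("T", 1, reference_region="A"))
        assert cols == ["Intercept", "region[B]"]
        assert X.shape == (3, 2)
        np.testing.assert_array_equal(X[:, 1], [0, 1, 1])

    @pytest.mark.parametrize("with_r", [False, True])
    def test_full_model_column_count(self, regime_table, with_r):
        # intercept + (R-1) regions + 3 age + 1 obesity + 1 childbirth
        # + 1 sex + 2 ses + 2 income + 3 urbanization [+ 1 visit indicator]
        stage = "T_given_I" if with_r else "T"
        sample = sv.select_sample(regime_table, stage)
        n_regions = sample["region"].nunique()
        X, _, cols = build_design(sample, StageModelSpec(stage, 3))
        expected = 1 + (n_regions - 1) + 3 + 1 + 1 + 1 + 2 + 2 + 3 + (1 if with_r else 0)
        assert len(cols) == expected
        assert X.shape[1] == expected

    def test_stage_I_guard_rejects_censored_rows(self):
        table = make_table([{"region": "A", "treated": 1, "visit_observed": 0},
                            {"region": "A"}, {"region": "B", "initial_visit": 1,
                                              "visit_observed": 1}])
        with pytest.raises(StateError, match="censored"):
            build_design(table, StageModelSpec("I", 1))

    def test_conditional_guard_rejects_nonvisitors(self):
        table = make_table([{"region": "A"}, {"region": "B"}])
        with pytest.raises(StateError, match="initial"):
            build_design(table, StageModelSpec("T_given_I", 1))

    def test_invalid_model_level(self):
        with pytest.raises(ValueError, match="model_level"):
            covariates_for_level(4)


class TestFitLogit:
    def test_intercept_only_balanced_outcomes(self):
        X = np.ones((4, 1))
        res = fit_logit(X, np.array([1.0, 1.0, 0.0, 0.0]))
        assert res.params[0] == pytest.approx(0.0, abs=1e-10)

    def test_saturated_model_reproduces_cell_rates(self):
        rows = []
        rows += [{"region": "A", "treated": 1}] * 20 + [{"region": "A"}] * 80
        rows += [{"region": "B", "treated": 1}] * 40 + [{"region": "B"}] * 60
        table = make_table(rows)
        est = sv.StageLogit(stage="T", model_level=1).fit(table)
        probs = est.predict_proba(pd.DataFrame({"region": ["A", "B"]}))
        assert probs[0] == pytest.approx(0.2, abs=1e-6)
        assert probs[1] == pytest.approx(0.4, abs=1e-6)

    def test_constant_outcome_rejected(self):
        table = make_table([{"region": "A", "treated": 1, "initial_visit": 1,
                             "visit_observed": 1}] * 5)
        with pytest.raises(ValueError, match="constant"):
            sv.StageLogit(stage="T", model_level=1).fit(table)

    def test_zero_event_region_flagged_not_dropped(self):
        rows = [{"region": "A", "treated": 1, "initial_visit": 1,
                 "visit_observed": 1}] * 5 + [{"region": "A"}] * 5
        rows += [{"region": "B"}] * 10  # region B: zero events
        table = make_table(rows)
        est = sv.StageLogit(stage="T", model_level=1).fit(table)
        assert "B" in est.beta_region_
        assert est.separated_
        assert est.beta_region_["B"] < -10  # probability numerically zero

    def test_agrees_with_statsmodels_logit(self, oracle_sample):
        """Grouped Newton fit vs the row-level statsmodels MLE (independent
        oracle): coefficients, covariance, log-likelihood and AIC."""
        sample = oracle_sample
        spec = StageModelSpec("I", 3)
        est = sv.StageLogit(stage="I", model_level=3).fit(sample)
        X, y, cols = build_design(sample, spec)
        oracle = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(est.params_, oracle.params, atol=1e-8)
        np.testing.assert_allclose(est.cov_params_, oracle.cov_params(), atol=1e-8)
        assert est.loglik_ == pytest.approx(oracle.llf, abs=1e-6)
        assert est.aic_ == pytest.approx(oracle.aic, abs=1e-6)

    def test_conditional_model_estimates_visit_indicator(self, regime_table):
        sample = sv.select_sample(regime_table, "T_given_I")
        est = sv.StageLogit(stage="T_given_I", model_level=2).fit(sample)
        assert est.pi_ is not None
        assert "visit_observed" in est.columns_

    def test_visit_indicator_dropped_when_constant(self):
        rows = [{"region": r, "initial_visit": 1, "visit_observed": 1,
                 "treated": t} for r in "AB" for t in (0, 1) for _ in range(5)]
        table = make_table(rows)
        with pytest.warns(UserWarning, match="visit indicator"):
            est = sv.StageLogit(stage="T_given_I", model_level=1).fit(table)
        assert est.pi_ is None


class TestMarginalEffects:
    def test_intercept_only_model_has_empty_table(self, regime_table):
        est = sv.StageLogit(stage="T", model_level=1).fit(regime_table)
        assert len(est.marginal_effects()) == 0

    def test_zero_coefficient_gives_zero_ame(self):
        rows = []
        for sex in (0, 1):
            rows += [{"region": "A", "sex_female": sex, "treated": 1,
                      "initial_visit": 1, "visit_observed": 1}] * 10
            rows += [{"region": "A", "sex_female": sex}] * 10
            rows += [{"region": "B", "sex_female": sex, "treated": 1,
                      "initial_visit": 1, "visit_observed": 1}] * 5
            rows += [{"region": "B", "sex_female": sex}] * 15
        table = make_table(rows)
        est = sv.StageLogit(stage="T", model_level=3).fit(table)
        ame = est.marginal_effects().set_index("term")
        assert ame.loc["sex_female[1]", "ame"] == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_statsmodels_margeff_for_binary_covariates(self, oracle_sample):
        sample = oracle_sample
        est = sv.StageLogit(stage="I", model_level=3).fit(sample)
        X, y, cols = build_design(sample, StageModelSpec("I", 3))
        oracle = sm.Logit(y, X).fit(disp=0).get_margeff(at="overall", dummy=True)
        ame = est.marginal_effects().set_index("term")
        for term in ("obesity[1]", "childbirth[1]", "sex_female[1]"):
            k = cols.index(term) - 1  # margeff table has no intercept row
            assert ame.loc[term, "ame"] == pytest.approx(oracle.margeff[k], abs=1e-10)
            assert ame.loc[term, "se"] == pytest.approx(oracle.margeff_se[k], abs=1e-8)

    def test_recovers_dgp_implied_sex_effect(self):
        """AME of being female at the visit stage vs a Monte-Carlo oracle that
        averages the DGP's probability difference over the population."""
        params = sv.referral_dominated_params(100_000, n_regions=6, seed=11)
        table = sv.simulate_claims(params)
        sample = sv.select_sample(table, "I")
        est = sv.StageLogit(stage="I", model_level=3).fit(sample)
        ame = est.marginal_effects().set_index("term")

        # oracle: true probability difference female-vs-male per individual
        from scipy.special import expit

        alpha = sample["region"].map(params.alpha_visit).to_numpy(dtype=float)
        age_eff = sample["age_cat"].astype(str).map(
            {"0-40": 0.0, **{k: float(v) for k, v in params.theta_visit["age_cat"].items()}}
        ).to_numpy(dtype=float)
        ses_eff = sample["ses_cat"].astype(str).map(
            {"high": 0.0, **{k: float(v) for k, v in params.gamma_visit["ses_cat"].items()}}
        ).to_numpy(dtype=float)
        base = alpha + age_eff + ses_eff
        sex_coef = float(params.gamma_visit["sex_female"])
        true_ame = float(np.mean(expit(base + sex_coef) - expit(base)))

        row = ame.loc["sex_female[1]"]
        assert row["ame"] == pytest.approx(true_ame, abs=3 * row["se"])


def test_adjusted_model_improves_aic_under_true_effects(regime_table):
    """With nonzero needs/preference effects in the truth, the fully adjusted
    model must fit better (lower AIC) than the crude one."""
    for stage in ("I", "T_given_I"):
        sample = sv.select_sample(regime_table, stage)
        aic1 = sv.StageLogit(stage=stage, model_level=1).fit(sample).aic_
        aic3 = sv.StageLogit(stage=stage, model_level=3).fit(sample).aic_
        assert aic3 < aic1
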
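"""Fixed-covariate standardization of regional probabilities."""

import pandas as pd
import pytest
from scipy.special import logit

import stagevar as sv
from stagevar.standardize import default_reference_covariates
from conftest import make_table


@pytest.fixture(scope="module")
def visit_model(regime_table):
    sample = sv.select_sample(regime_table, "I")
    return sv.StageLogit(stage="I", model_level=3).fit(sample), sample


class TestPredictIndividual:
    def test_reference_individual_probability(self):
        # saturated one-region model with rate 0.2: reference individual's
        # prediction is invlogit(logit(0.2)) = 0.2
        rows = [{"region": "A", "treated": 1, "initial_visit": 1,
                 "visit_observed": 1}] * 20 + [{"region": "A"}] * 80
        rows += [{"region": "B", "treated": 1, "initial_visit": 1,
                  "visit_observed": 1}] * 50 + [{"region": "B"}] * 50
        est = sv.StageLogit(stage="T", model_level=1).fit(make_table(rows))
        assert est.beta0_ == pytest.approx(float(logit(0.2)), abs=1e-8)
        p = sv.predict_individual(est, {"region": "A"})
        assert p == pytest.approx(0.2, abs=1e-8)

    def test_logistic_symmetry(self, visit_model):
        est, _ = visit_model
        ref = default_reference_covariates()
        p = sv.predict_individual(est, {"region": est.regions_[0], **ref})
        assert 0.0 < p < 1.0
        # mirrored linear predictor: probabilities sum to 1
        mirrored = est.params_ @ est.design_.region_prediction_rows(ref)[0]
        from scipy.special import expit
        assert expit(mirrored) + expit(-mirrored) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_region_rejected(self, visit_model):
        est, _ = visit_model
        with pytest.raises(ValueError, match="unknown region"):
            sv.predict_individual(est, {"region": "nowhere"})


class TestStandardizedRegionalProbs:
    def test_crude_model_equals_observed_rates(self, regime_table):
        sample = sv.select_sample(regime_table, "I")
        est = sv.StageLogit(stage="I", model_level=1).fit(sample)
        regional = sv.standardized_regional_probs(est, sample)
        observed = sample.groupby("region", observed=True)["initial_visit"].mean()
        for region, p in regional.probs.items():
            assert p == pytest.approx(observed[region], abs=1e-6)

    def test_within_region_constancy(self, visit_model):
        est, sample = visit_model
        ref = default_reference_covariates()
        overridden = sample.head(4000).copy()
        for cov, lev in ref.items():
            if cov in overridden.columns:
                overridden[cov] = lev
        preds = pd.Series(est.predict_proba(overridden),
                          index=overridden["region"].astype(str))
        spread = preds.groupby(level=0).agg(lambda s: s.max() - s.min())
        assert (spread <= 1e-12).all()

    def test_regional_mean_of_predictions_matches(self, visit_model):
        est, sample = visit_model
        regional = sv.standardized_regional_probs(est, sample)
        ref = default_reference_covariates()
        overridden = sample.copy()
        for cov, lev in ref.items():
            if cov in overridden.columns:
                overridden[cov] = lev
        preds = pd.DataFrame({"region": overridden["region"].astype(str),
                              "p": est.predict_proba(overridden)})
        means = preds.groupby("region")["p"].mean()
        for region, p in regional.probs.items():
            assert p == pytest.approx(means[region], abs=1e-12)

    def test_null_coefficient_reference_invariance(self, visit_model):
        """Changing the reference level of a covariate whose coefficient is
        forced to zero leaves the standardized probabilities unchanged."""
        est, sample = visit_model
        est2 = sv.StageLogit(stage="I", model_level=3).fit(sample)
        k = est2.columns_.index("income_cat[middle]")
        est2.params_[k] = 0.0
        a = sv.standardized_regional_probs(est2, sample)
        b = sv.standardized_regional_probs(
            est2, sample, reference_covariates={"income_cat": "middle"})
        assert a.probs == b.probs

    def test_monotonic_in_region_effect(self, visit_model):
        est, sample = visit_model
        bumped = sv.StageLogit(stage="I", model_level=3).fit(sample)
        target = bumped.regions_[2]
        k = bumped.columns_.index(f"region[{target}]")
        bumped.params_[k] += 0.3
        base = sv.standardized_regional_probs(est, sample)
        moved = sv.standardized_regional_probs(bumped, sample)
        assert moved.probs[target] > base.probs[target]
        for region in base.probs:
            if region != target:
                assert moved.probs[region] == pytest.approx(base.probs[region], abs=1e-12)

    def test_mean_sd_match_brute_force(self, visit_model):
        est, sample = visit_model
        regional = sv.standardized_regional_probs(est, sample)
        vals = list(regional.probs.values())
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert regional.mean_prob == pytest.approx(mean, abs=1e-15)
        assert regional.sd_prob() == pytest.approx(sd, abs=1e-15)

    def test_unknown_region_in_table_rejected(self, visit_model):
        est, sample = visit_model
        alien = sample.head(5).copy()
        alien["region"] = "Z99"
        with pytest.raises(ValueError, match="Z99"):
            sv.standardized_regional_probs(est, alien)

    def test_bad_reference_level_rejected(self, visit_model):
        est, sample = visit_model
        with pytest.raises(ValueError, match="declared level"):
            sv.standardized_regional_probs(
                est, sample, reference_covariates={"ses_cat": "royal"})

    def test_weighted_summary_available(self, visit_model):
        est, sample = visit_model
        regional = sv.standardized_regional_probs(est, sample)
        m, sd = regional.weighted_mean_sd()
        assert 0 < m < 1 and sd >= 0
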
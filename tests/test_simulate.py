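"""The synthetic gatekept-claims generator and its closed-form CVUs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import stagevar as sv
from stagevar.models import StateError
from stagevar.simulate import DgpParams, regional_alphas_from_probs


def _flat_params(**overrides):
    regions = ["A", "B", "C", "D"]
    defaults = dict(
        n_individuals=1000,
        regions=regions,
        alpha_visit={r: 0.0 for r in regions},
        alpha_treat={r: 0.0 for r in regions},
        seed=7,
    )
    defaults.update(overrides)
    return DgpParams(**defaults)


class TestGeneratePopulation:
    def test_deterministic_and_balanced(self):
        p = _flat_params()
        a = sv.generate_population(p)
        b = sv.generate_population(p)
        pd.testing.assert_frame_equal(a, b)
        counts = a["region"].value_counts()
        assert set(counts.index) == {"A", "B", "C", "D"}
        # equal weights: each region near n/4
        assert (np.abs(counts - 250) < 4 * np.sqrt(1000 * 0.25 * 0.75)).all()

    def test_degenerate_covariate_distribution(self):
        p = _flat_params(covariate_dist={"sex_female": 1.0})
        pop = sv.generate_population(p)
        assert (pop["sex_female"] == 1).all()

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="n_individuals"):
            _flat_params(n_individuals=0)

    def test_bad_probability_sum_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            _flat_params(covariate_dist={"ses_cat": {"high": 0.5, "low": 0.5, "middle": 0.5}})

    def test_missing_region_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha_visit"):
            _flat_params(alpha_visit={"A": 0.0})


class TestSimulateJourney:
    def test_symmetric_bernoulli_rates(self):
        p = _flat_params(n_individuals=50_000, p_censor_visit=0.0)
        tab = sv.simulate_claims(p)
        by_region = tab.groupby("region", observed=True)["initial_visit"].agg(["mean", "count"])
        se = np.sqrt(0.25 / by_region["count"])
        assert (np.abs(by_region["mean"] - 0.5) < 3 * se).all()

    def test_gatekeeping_invariant(self, regime_table):
        treated = regime_table[regime_table["treated"] == 1]
        assert (treated["initial_visit"] == 1).all()

    def test_degenerate_treatment_stage(self):
        p = _flat_params(n_individuals=5000,
                         alpha_treat={r: -30.0 for r in ["A", "B", "C", "D"]})
        tab = sv.simulate_claims(p)
        assert tab["treated"].sum() == 0

    def test_full_censoring(self):
        p = _flat_params(n_individuals=5000, p_censor_visit=1.0)
        tab = sv.simulate_claims(p)
        treated = tab[tab["treated"] == 1]
        assert len(treated) > 0
        assert (treated["visit_observed"] == 0).all()
        untreated_visits = tab[(tab["treated"] == 0) & (tab["initial_visit"] == 1)]
        assert (untreated_visits["visit_observed"] == 1).all()

    def test_same_seed_byte_identical(self, tmp_path):
        p = _flat_params(n_individuals=2000)
        a, b = sv.simulate_claims(p), sv.simulate_claims(p)
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        sv.write_claims(a, fa)
        sv.write_claims(b, fb)
        assert fa.read_bytes() == fb.read_bytes()

    def test_unset_covariates_rejected(self):
        p = _flat_params()
        pop = sv.generate_population(p).drop(columns=["obesity"])
        with pytest.raises(StateError, match="obesity"):
            sv.simulate_journey(pop, p)


class TestTrueStageCvus:
    def test_no_dispersion_gives_zero(self):
        p = _flat_params()
        assert sv.true_stage_cvus(p) == (0.0, 0.0, 0.0)

    def test_hand_computed_three_region_case(self):
        # visit probs (0.1, 0.2, 0.3): sample SD 0.1, mean 0.2 -> CVU 0.5;
        # conditional probs constant 0.5 -> CVU 0; unconditional probs
        # (0.05, 0.10, 0.15) scale the visit probs by 0.5 -> CVU unchanged.
        regions = ["a", "b", "c"]
        p = DgpParams(
            n_individuals=10,
            regions=regions,
            alpha_visit=regional_alphas_from_probs(regions, [0.1, 0.2, 0.3]),
            alpha_treat={r: float(logit(0.5)) for r in regions},
        )
        t = sv.true_stage_cvus(p)
        assert t.cvu_I == pytest.approx(0.5, abs=1e-12)
        assert t.cvu_TI == pytest.approx(0.0, abs=1e-12)
        assert t.cvu_T == pytest.approx(0.5, abs=1e-12)

    def test_region_permutation_invariance(self):
        regions = ["a", "b", "c"]
        probs = dict(zip(regions, [0.1, 0.25, 0.4]))
        t1 = sv.true_stage_cvus(DgpParams(
            n_individuals=1, regions=regions,
            alpha_visit=regional_alphas_from_probs(regions, [probs[r] for r in regions]),
            alpha_treat={r: 0.0 for r in regions}))
        perm = ["c", "a", "b"]
        t2 = sv.true_stage_cvus(DgpParams(
            n_individuals=1, regions=perm,
            alpha_visit=regional_alphas_from_probs(perm, [probs[r] for r in perm]),
            alpha_treat={r: 0.0 for r in perm}))
        assert t1 == t2

    def test_fewer_than_two_regions_rejected(self):
        p = DgpParams(n_individuals=1, regions=["solo"],
                      alpha_visit={"solo": 0.0}, alpha_treat={"solo": 0.0})
        with pytest.raises(ValueError, match="2 regions"):
            sv.true_stage_cvus(p)

    def test_reference_assignment_shifts_through_effects(self):
        p = _flat_params(
            alpha_visit={"A": -1.0, "B": 0.0, "C": 1.0, "D": 0.5},
            theta_visit={"obesity": 2.0},
        )
        base = sv.true_stage_cvus(p)
        shifted = sv.true_stage_cvus(p, reference_covariates={"obesity": 1})
        assert base.cvu_I != shifted.cvu_I

    def test_equal_dispersion_factory_nulls_h2(self):
        p = sv.equal_stage_dispersion_params(1000, n_regions=8, cv=0.12)
        t = sv.true_stage_cvus(p)
        assert t.cvu_I == pytest.approx(t.cvu_TI, abs=1e-12)
        assert t.cvu_I == pytest.approx(0.12, abs=1e-12)

    def test_referral_dominated_factory_orders_stages(self):
        t = sv.true_stage_cvus(sv.referral_dominated_params(1000, n_regions=30))
        assert t.cvu_I > t.cvu_T > t.cvu_TI


def test_yaml_round_trip(tmp_path):
    p = sv.referral_dominated_params(500, n_regions=3, seed=9)
    path = tmp_path / "dgp.yaml"
    p.to_yaml(path)
    q = DgpParams.from_yaml(path)
    assert q.to_dict() == p.to_dict()
    pd.testing.assert_frame_equal(sv.simulate_claims(p), sv.simulate_claims(q))
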
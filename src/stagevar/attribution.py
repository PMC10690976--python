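"""End-to-end attribution of regional practice variation to journey stages."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from . import claims
from .models import StageLogit, StageModelSpec
from .standardize import standardized_regional_probs
from .variation import (
    HYPOTHESIS_PAIRS,
    bootstrap_cvus,
    test_cvu_difference,
)

__all__ = ["PracticeVariationAttribution"]


class PracticeVariationAttribution(BaseEstimator):
    """Fit the full stage-attribution analysis on a policy-holder table.

    For every journey stage (treatment, initial visit, treatment given a
    visit) and every requested adjustment level, fits the region-dummy logit
    on the stage's analysis sample, computes covariate-standardized regional
    probabilities, the per-stage CVU, a joint bootstrap of all CVUs, and the
    three pairwise hypothesis tests.

    Parameters
    ----------
    model_levels : adjustment levels to run (subset of {1, 2, 3}).
    reference_region : region absorbed into the intercept (default: first
        region in sorted order).
    reference_covariates : covariate assignment at which predictions are
        standardized; defaults to each covariate's reference category and an
        observed visit.
    include_visit_indicator : include the observed-vs-assumed visit term in
        the conditional-stage models.
    n_boot : bootstrap replicates (the reference procedure uses 10,000).
    level : two-sided test size for intervals and hypothesis decisions.
    stratify_by_region : resample within regions, preserving region sizes.
    random_state : master seed for the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    models_ : dict ``(stage, model_level) -> StageLogit``.
    regional_probs_ : dict ``(stage, model_level) -> RegionalProbabilities``.
    cvus_ : dict ``(stage, model_level) -> float`` (point CVUs).
    boot_ : :class:`stagevar.variation.BootstrapCvus`.
    cvu_estimates_ : DataFrame of point CVU, bootstrap SD and percentile CI.
    hypothesis_results_ : DataFrame with one row per (hypothesis, level).
    """

    def __init__(
        self,
        model_levels: Sequence[int] = (1, 2, 3),
        reference_region: str | None = None,
        reference_covariates: Mapping | None = None,
        include_visit_indicator: bool = True,
        n_boot: int = 10_000,
        level: float = 0.05,
        stratify_by_region: bool = True,
        random_state: int | None = None,
    ):
        self.model_levels = model_levels
        self.reference_region = reference_region
        self.reference_covariates = reference_covariates
        self.include_visit_indicator = include_visit_indicator
        self.n_boot = n_boot
        self.level = level
        self.stratify_by_region = stratify_by_region
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "PracticeVariationAttribution":
        table = claims.validate_claims(X)
        levels = list(self.model_levels)
        specs = [
            StageModelSpec(
                stage=st,
                model_level=lvl,
                reference_region=self.reference_region,
                include_visit_indicator=self.include_visit_indicator,
            )
            for st in claims.STAGES
            for lvl in levels
        ]

        self.models_ = {}
        self.regional_probs_ = {}
        self.cvus_ = {}
        for spec in specs:
            sample = claims.select_sample(table, spec.stage)
            est = StageLogit(
                stage=spec.stage,
                model_level=spec.model_level,
                reference_region=self.reference_region,
                include_visit_indicator=self.include_visit_indicator,
            ).fit(sample)
            regional = standardized_regional_probs(est, sample, self.reference_covariates)
            key = (spec.stage, spec.model_level)
            self.models_[key] = est
            self.regional_probs_[key] = regional
            self.cvus_[key] = regional.sd_prob() / regional.mean_prob

        self.boot_ = bootstrap_cvus(
            table,
            specs,
            reference_covariates=self.reference_covariates,
            n_boot=self.n_boot,
            seed=self.random_state,
            stratify_by_region=self.stratify_by_region,
        )

        est_rows = []
        for st in claims.STAGES:
            for lvl in levels:
                e = self.boot_.cvu_estimate(st, lvl, level=self.level)
                est_rows.append(vars(e))
        self.cvu_estimates_ = pd.DataFrame(est_rows)

        hyp_rows = []
        for hid in HYPOTHESIS_PAIRS:
            for lvl in levels:
                r = test_cvu_difference(self.boot_, hid, model_level=lvl, level=self.level)
                row = vars(r).copy()
                row["delta_ci_low"], row["delta_ci_high"] = row.pop("delta_ci")
                row.pop("pair")
                hyp_rows.append(row)
        self.hypothesis_results_ = pd.DataFrame(hyp_rows)
        return self

    def summary(self) -> str:
        """Human-readable per-stage CVU and hypothesis summary."""
        if not hasattr(self, "cvu_estimates_"):
            raise RuntimeError("not fitted")
        lines = ["Standardized regional dispersion (CVU = SD/mean across regions)"]
        for _, r in self.cvu_estimates_.iterrows():
            lines.append(
                f"  {r.stage:>9s}  model {r.model_level}: "
                f"CVU = {r.cvu:.3f}  (boot SD {r.boot_sd:.3f}, "
                f"{100 * (1 - self.level):.0f}% CI {r.ci_low:.3f}-{r.ci_high:.3f})"
            )
        lines.append("Hypothesis tests on CVU differences")
        for _, r in self.hypothesis_results_.iterrows():
            verdict = "rejected" if r.reject else "not rejected"
            lines.append(
                f"  {r.hypothesis_id} model {r.model_level}: delta = {r.delta:+.3f} "
                f"CI ({r.delta_ci_low:+.3f}, {r.delta_ci_high:+.3f}), "
                f"p = {r.p_value:.4f} -> {verdict}"
            )
        return "\n".join(lines)
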
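"""Covariate-standardized regional probabilities.

Direct standardization by fixed-covariate prediction: every individual's
outcome probability is predicted with the needs and preference covariates
overridden by a single reference assignment, so only the regional effect
varies.  Within a region every individual then receives the identical value
``invlogit(b0 + b_region [+ theta.Xref + gamma.Zref + pi])`` and the
regional mean of predictions equals that value.  The choice of reference
assignment shifts all regions by a common logit offset — it changes the CVU
level but not the ranking of regions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import claims
from .models import StageLogit

__all__ = [
    "RegionalProbabilities",
    "default_reference_covariates",
    "predict_individual",
    "standardized_regional_probs",
]


def default_reference_covariates() -> dict:
    """The model reference categories, plus an observed visit (R=1)."""
    ref = {cov: levels[0] for cov, levels in claims.CATEGORICAL_LEVELS.items()
           if cov in claims.COVARIATES}
    ref["visit_observed"] = 1
    return ref


@dataclass
class RegionalProbabilities:
    """Standardized per-region probabilities for one (stage, model) pair."""

    stage: str
    model_level: int
    probs: dict = field(default_factory=dict)  # region -> probability
    n_per_region: dict = field(default_factory=dict)

    def __post_init__(self):
        for r, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"region {r!r}: probability {p} outside [0, 1]")

    @property
    def regions(self) -> list:
        return list(self.probs)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.probs.values()), dtype=float)

    @property
    def mean_prob(self) -> float:
        """Unweighted mean over regions."""
        return float(self.values.mean())

    def sd_prob(self, ddof: int = 1) -> float:
        """SD over regions (sample SD by default; regions are treated as a
        draw from a dispersion process)."""
        return float(self.values.std(ddof=ddof))

    def weighted_mean_sd(self) -> tuple[float, float]:
        """Population-weighted alternative (off the default CVU path)."""
        w = np.asarray([self.n_per_region[r] for r in self.probs], dtype=float)
        w = w / w.sum()
        m = float(w @ self.values)
        v = float(w @ (self.values - m) ** 2)
        return m, float(np.sqrt(v))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": list(self.probs),
                "stage": self.stage,
                "model_level": self.model_level,
                "prob": list(self.probs.values()),
                "n": [self.n_per_region.get(r, 0) for r in self.probs],
            }
        )


def predict_individual(model: StageLogit, record: Mapping) -> float:
    """Predicted probability for a single covariate assignment."""
    df = pd.DataFrame([dict(record)])
    return float(model.predict_proba(df)[0])


def standardized_regional_probs(
    model: StageLogit,
    table: pd.DataFrame,
    reference_covariates: Mapping | None = None,
) -> RegionalProbabilities:
    """Standardized probability per region under a fixed covariate assignment.

    Each individual's prediction is computed with covariates overridden by
    ``reference_covariates`` (region kept as observed); predictions are
    summed within region and divided by the regional count.  Because the
    covariates are fixed, that mean equals the common per-region value.

    Raises if the table contains a region absent from the fitted model.
    """
    model._check_fitted()
    ref = dict(default_reference_covariates())
    if reference_covariates:
        for cov, lev in reference_covariates.items():
            if cov != "visit_observed" and cov not in claims.COVARIATES:
                raise ValueError(f"unknown reference covariate {cov!r}")
            if cov in claims.CATEGORICAL_LEVELS and str(lev) not in tuple(
                str(x) for x in claims.CATEGORICAL_LEVELS[cov]
            ):
                raise ValueError(
                    f"reference level {lev!r} not a declared level of {cov!r}"
                )
            ref[cov] = lev

    counts = table["region"].astype(str).value_counts()
    missing = sorted(set(counts.index) - set(model.regions_))
    if missing:
        raise ValueError(
            f"region(s) present in table but absent from the model: {missing}"
        )

    rows = model.design_.region_prediction_rows(ref)
    values = expit(rows @ model.params_)
    spec = model._spec()
    probs = {}
    n_per = {}
    for region, value in zip(model.regions_, values):
        if region in counts.index:
            probs[region] = float(value)
            n_per[region] = int(counts[region])
    return RegionalProbabilities(
        stage=spec.stage,
        model_level=spec.model_level,
        probs=probs,
        n_per_region=n_per,
    )
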